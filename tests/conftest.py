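import numpy as np
import pandas as pd
import pytest

import moodmine as mm
from moodmine.notes import NoteGenConfig, generate_notes, make_sentence_corpus


@pytest.fixture(scope="session")
def small_cohort():
    """500-patient stratified cohort without outcomes, with notes attached."""
    cfg = mm.CohortConfig(n=500, mode="stratified", seed=7)
    cohort = mm.generate_cohort(cfg, outcomes=False)
    sentences = generate_notes(cohort, NoteGenConfig(documentation_sensitivity=1.0, seed=3))
    return cohort, sentences


@pytest.fixture(scope="session")
def mid_cohort():
    """8000-patient model-mode cohort with outcomes (shared across tests)."""
    cfg = mm.CohortConfig(n=8000, mode="model", seed=11)
    return mm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_corpus():
    """Default labeled sentence corpus (3000 sentences per construct)."""
    return make_sentence_corpus(3000, misspelling_rate=0.1, seed=0)
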