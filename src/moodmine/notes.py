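"""Synthetic clinical-note generator with ground-truth sentence labels.

Emits dated free-text sentences per patient covering three affective
constructs (mood, affect, emotion). Positive sentences describe instability
of the construct; distractors include negated mentions ("no evidence of mood
instability"), stable-mood statements and unrelated clinical filler. A fixed
misspelling table corrupts modifier tokens at a configurable rate.

The generator also produces a standalone labeled sentence corpus (without
patients) for classifier development. Its composition is deliberately not
linearly separable: a small family of "temporal" sentences uses the same bag
of words for positive and negative readings ("previously stable mood now
unstable" vs "previously unstable mood now stable"), so a bag-of-words model
faces an irreducible mid-probability cluster. This reproduces the regime in
which a probability threshold trades recall for precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KEYWORDS",
    "MODIFIERS",
    "MISSPELLINGS",
    "NoteGenConfig",
    "inject_misspelling",
    "generate_notes",
    "make_sentence_corpus",
    "write_notes_jsonl",
    "read_notes_jsonl",
]

KEYWORDS = ("mood", "affect", "emotion")

# Modifier bank (instability-relevant); the first three are mandatory
# gazetteer terms and always present.
MODIFIERS = (
    "instability",
    "dysfunction",
    "irregular",
    "unstable",
    "labile",
    "fluctuating",
    "erratic",
    "volatile",
    "changeable",
    "swings",
)

# Fixed misspelling table (single-character substitutions/deletions seen in
# routine clinical typing).
MISSPELLINGS = {
    "unstable": "unstble",
    "labile": "lible",
    "fluctuating": "fluctating",
    "erratic": "eratic",
    "volatile": "volitile",
    "instability": "instabilty",
    "dysfunction": "disfunction",
    "irregular": "iregular",
    "swings": "swigns",
    "changeable": "changable",
}

POSITIVE_TEMPLATES = (
    "{k} has been {m} over the past week",
    "on examination the patient's {k} was markedly {m}",
    "patient reports {m} {k} since starting treatment",
    "ongoing {k} {m} noted during review",
    "carer describes {k} as {m} and difficult to predict",
    "{k} very up and down recently with frequent {m} episodes",
)

# Same token bag, opposite labels: positive reading first. The modifier is
# fixed and never misspelled, so all temporal sentences for a construct share
# one feature vector; a bag-of-words model must give them a single common
# probability (~ their positive fraction).
TEMPORAL_POSITIVE = "previously stable {k} now unstable"
TEMPORAL_NEGATIVE = "previously unstable {k} now stable"

NEGATION_TEMPLATES = (
    "no evidence of {k} instability",
    "denies any {m} {k}",
    "{k} not {m} today and appears settled",
    "no further {k} swings reported this month",
    "nil {m} {k} elicited at interview",
)

STABLE_TEMPLATES = (
    "{k} stable throughout the assessment",
    "{k} remains settled on current medication",
    "objectively euthymic {k} today",
)

FILLER_TEMPLATES = (
    "attended outpatient clinic with care coordinator",
    "medication adherence was discussed at length",
    "sleep and appetite reported as unremarkable",
    "plan to review in four weeks time",
    "referred to community team for ongoing support",
)


@dataclass
class NoteGenConfig:
    """Configuration for patient note generation."""

    misspelling_rate: float = 0.1
    distractor_rate: float = 0.8  # probability a note carries >=1 distractor
    documentation_sensitivity: float = 1.0
    notes_per_patient: tuple[int, int] = (2, 4)
    sentences_per_note: tuple[int, int] = (2, 5)
    horizon_days: int = 180  # note dates uniform in [presentation, +horizon]
    window_days: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("misspelling_rate", "distractor_rate", "documentation_sensitivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def inject_misspelling(
    word: str, rng: np.random.Generator | None = None, fallback: bool = False
) -> str:
    """Map a word to its fixed misspelled variant.

    Words absent from the table are returned unchanged unless ``fallback`` is
    enabled, in which case a deterministic (given ``rng``) adjacent-character
    transposition is applied to words of length >= 3.
    """
    if word in MISSPELLINGS:
        return MISSPELLINGS[word]
    if fallback and rng is not None and len(word) >= 3:
        i = int(rng.integers(0, len(word) - 1))
        return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    return word


def _maybe_misspell(modifier: str, rate: float, rng: np.random.Generator) -> str:
    if rate > 0 and rng.random() < rate:
        return inject_misspelling(modifier)
    return modifier


def _positive_sentence(keyword: str, rate: float, rng: np.random.Generator) -> str:
    template = POSITIVE_TEMPLATES[rng.integers(0, len(POSITIVE_TEMPLATES))]
    modifier = _maybe_misspell(MODIFIERS[rng.integers(0, len(MODIFIERS))], rate, rng)
    return template.format(k=keyword, m=modifier)


def _distractor_sentence(keyword: str, rate: float, rng: np.random.Generator) -> str:
    u = rng.random()
    if u < 0.45:
        template = NEGATION_TEMPLATES[rng.integers(0, len(NEGATION_TEMPLATES))]
        modifier = _maybe_misspell(MODIFIERS[rng.integers(0, len(MODIFIERS))], rate, rng)
        return template.format(k=keyword, m=modifier)
    if u < 0.75:
        return STABLE_TEMPLATES[rng.integers(0, len(STABLE_TEMPLATES))].format(k=keyword)
    return FILLER_TEMPLATES[rng.integers(0, len(FILLER_TEMPLATES))]


def generate_notes(patients: pd.DataFrame, config: NoteGenConfig) -> pd.DataFrame:
    """Generate dated sentences for every patient.

    ``patients`` must carry ``patient_id``, ``presentation_date`` and
    ``mi_true``. Exposure-positive patients receive at least one positive
    sentence dated within the documentation window with probability
    ``documentation_sensitivity``; exposure-negative patients never receive a
    positive sentence. Returns one row per sentence with ground-truth
    ``construct`` and ``label_true`` retained for evaluation only.
    """
    if not POSITIVE_TEMPLATES or not NEGATION_TEMPLATES:
        raise ValueError("template banks must be non-empty")
    rng = np.random.default_rng(config.seed)
    lo_n, hi_n = config.notes_per_patient
    lo_s, hi_s = config.sentences_per_note
    rows = []
    note_id = 0
    sentence_id = 0
    for pid, pres, mi in zip(
        patients["patient_id"].to_numpy(),
        np.asarray(patients["presentation_date"], dtype="datetime64[D]"),
        patients["mi_true"].to_numpy(),
    ):
        n_notes = int(rng.integers(lo_n, hi_n + 1))
        documented = bool(mi) and rng.random() < config.documentation_sensitivity
        doc_note = int(rng.integers(0, n_notes)) if documented else -1
        for j in range(n_notes):
            if j == doc_note:
                date = pres + np.timedelta64(
                    int(rng.integers(0, config.window_days + 1)), "D"
                )
            else:
                date = pres + np.timedelta64(
                    int(rng.integers(0, config.horizon_days + 1)), "D"
                )
            n_sent = int(rng.integers(lo_s, hi_s + 1))
            sentences = []
            if j == doc_note:
                kw = KEYWORDS[rng.integers(0, len(KEYWORDS))]
                sentences.append(
                    (_positive_sentence(kw, config.misspelling_rate, rng), kw, 1)
                )
            while len(sentences) < n_sent:
                kw = KEYWORDS[rng.integers(0, len(KEYWORDS))]
                if rng.random() < config.distractor_rate:
                    text = _distractor_sentence(kw, config.misspelling_rate, rng)
                else:
                    text = FILLER_TEMPLATES[rng.integers(0, len(FILLER_TEMPLATES))]
                sentences.append((text, "none", 0))
            order = rng.permutation(len(sentences))
            for idx in order:
                text, construct, label = sentences[idx]
                rows.append(
                    (sentence_id, note_id, int(pid), date, text, construct, int(label))
                )
                sentence_id += 1
            note_id += 1
    return pd.DataFrame(
        rows,
        columns=[
            "sentence_id",
            "note_id",
            "patient_id",
            "date",
            "text",
            "construct",
            "label_true",
        ],
    )


def make_sentence_corpus(
    n_per_construct: int = 3000,
    misspelling_rate: float = 0.1,
    seed: int = 0,
    mix: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Standalone labeled sentence corpus for classifier development.

    Default composition per construct: 33% clean positives, 20% temporally
    ambiguous sentences (60% of which are positive), 28% negated mentions,
    11% stable statements and 8% unrelated filler.
    """
    mix = mix or {
        "positive": 0.33,
        "temporal": 0.20,
        "negation": 0.28,
        "stable": 0.11,
        "filler": 0.08,
    }
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("corpus mix must sum to 1")
    rng = np.random.default_rng(seed)
    kinds = list(mix)
    probs = np.array([mix[k] for k in kinds])
    rows = []
    sid = 0
    for kw in KEYWORDS:
        for _ in range(n_per_construct):
            kind = kinds[rng.choice(len(kinds), p=probs)]
            if kind == "positive":
                text, label = _positive_sentence(kw, misspelling_rate, rng), 1
            elif kind == "temporal":
                label = int(rng.random() < 0.6)
                template = TEMPORAL_POSITIVE if label else TEMPORAL_NEGATIVE
                text = template.format(k=kw)
            elif kind == "negation":
                template = NEGATION_TEMPLATES[rng.integers(0, len(NEGATION_TEMPLATES))]
                modifier = _maybe_misspell(
                    MODIFIERS[rng.integers(0, len(MODIFIERS))], misspelling_rate, rng
                )
                text, label = template.format(k=kw, m=modifier), 0
            elif kind == "stable":
                text, label = (
                    STABLE_TEMPLATES[rng.integers(0, len(STABLE_TEMPLATES))].format(k=kw),
                    0,
                )
            else:
                text, label = FILLER_TEMPLATES[rng.integers(0, len(FILLER_TEMPLATES))], 0
            rows.append((sid, kw, text, label))
            sid += 1
    return pd.DataFrame(rows, columns=["sentence_id", "construct", "text", "label"])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_notes_jsonl(sentences: pd.DataFrame, notes_path, labels_path=None) -> None:
    """Write notes as JSONL (one note per line); labels to a separate CSV.

    The JSONL file carries only id, patient id, date and raw text; ground
    truth goes to ``labels_path`` so the extraction pipeline cannot see it.
    """
    with open(notes_path, "w") as fh:
        for note_id, grp in sentences.groupby("note_id"):
            rec = {
                "note_id": int(note_id),
                "patient_id": int(grp["patient_id"].iloc[0]),
                "date": str(np.asarray(grp["date"].iloc[0], dtype="datetime64[D]")),
                "text": ". ".join(grp["text"]) + ".",
            }
            fh.write(json.dumps(rec) + "\n")
    if labels_path is not None:
        sentences[["sentence_id", "note_id", "patient_id", "construct", "label_true"]].to_csv(
            labels_path, index=False
        )


def read_notes_jsonl(path) -> pd.DataFrame:
    """Read a JSONL note file back into per-sentence rows."""
    rows = []
    sid = 0
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            for sent in _split_sentences(rec["text"]):
                rows.append(
                    (sid, rec["note_id"], rec["patient_id"], np.datetime64(rec["date"]), sent)
                )
                sid += 1
    return pd.DataFrame(rows, columns=["sentence_id", "note_id", "patient_id", "date", "text"])


def _split_sentences(text: str) -> list[str]:
    import re

    spans = re.split(r"[.?!\n]+", text)
    return [s.strip() for s in spans if s.strip()]
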