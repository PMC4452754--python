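"""Generate clinical notes, induce a modifier gazetteer, extract candidates.

The gazetteer stage scans a +/-2-token window around each construct keyword
(mood / affect / emotion), keeps the most frequent instability-relevant
modifiers, and extracts every sentence containing a keyword plus a modifier.
"""

import moodmine as mm
from moodmine.gazetteer import (
    build_gazetteer,
    default_gazetteers,
    extract_candidate_sentences,
    find_modifier_candidates,
)
from moodmine.notes import NoteGenConfig, generate_notes

cohort = mm.generate_cohort(mm.CohortConfig(n=300, mode="stratified", seed=2), outcomes=False)
sentences = generate_notes(cohort, NoteGenConfig(seed=2))
print(f"{len(sentences)} sentences, {int(sentences['label_true'].sum())} truly positive")

freq = find_modifier_candidates(sentences["text"], "mood", window=2)
print("\nmost frequent tokens near 'mood':")
for token, count in freq.most_common(8):
    print(f"  {token:<12s} {count}")

induced = build_gazetteer(freq, "mood", top_k=10)
print(f"\ninduced gazetteer ({len(induced.modifiers)} entries, mandatory terms included):")
print("  " + ", ".join(sorted(induced.modifiers)))

candidates = extract_candidate_sentences(sentences, default_gazetteers())
print(f"\ncandidate (sentence, construct) pairs: {len(candidates)}")
print("sample candidate:", candidates["text"].iloc[0])
# Candidates include negated mentions ("no evidence of mood instability");
# separating those from true positives is the classifier's job.
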