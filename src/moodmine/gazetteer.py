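"""Gazetteer induction and candidate-sentence extraction.

The pre-classifier stage: for each construct keyword (mood, affect,
emotion), modifier tokens are harvested from a +/-2-token context window
around keyword occurrences, the most frequent instability-relevant ones are
kept, and sentences containing the keyword plus at least one modifier are
extracted as candidates for classification. Matching is whole-token and
case-insensitive; misspellings are handled by explicit gazetteer entries,
never by stemming.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .notes import KEYWORDS, MODIFIERS, MISSPELLINGS

__all__ = [
    "MANDATORY_TERMS",
    "Gazetteer",
    "tokenize",
    "find_modifier_candidates",
    "build_gazetteer",
    "default_gazetteers",
    "extract_candidate_sentences",
    "write_gazetteer",
    "read_gazetteer",
]

# Always included in every application's gazetteer regardless of corpus
# frequency, because they are standard descriptors of the construct.
MANDATORY_TERMS = frozenset({"instability", "dysfunction", "irregular"})

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any non-alphanumeric run, dropping empties."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Gazetteer:
    keyword: str
    modifiers: frozenset[str]

    def __post_init__(self):
        if not MANDATORY_TERMS <= self.modifiers:
            object.__setattr__(self, "modifiers", self.modifiers | MANDATORY_TERMS)
        for tok in self.modifiers:
            if not tok or tok != tok.lower():
                raise ValueError(f"gazetteer entries must be non-empty lowercase: {tok!r}")


def find_modifier_candidates(
    sentences: Iterable[str], keyword: str, window: int = 2
) -> Counter:
    """Count tokens occurring within ``window`` tokens of each keyword use.

    Every keyword occurrence contributes its own window (overlapping windows
    count tokens repeatedly); windows are truncated at sentence boundaries.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    counts: Counter = Counter()
    for sentence in sentences:
        tokens = tokenize(sentence)
        for i, tok in enumerate(tokens):
            if tok != keyword:
                continue
            lo = max(0, i - window)
            hi = min(len(tokens), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    counts[tokens[j]] += 1
    return counts


def build_gazetteer(
    freq_table: Mapping[str, int],
    keyword: str,
    top_k: int = 10,
    manual_additions: Iterable[str] = (),
) -> Gazetteer:
    """Top-k tokens by frequency (ties lexicographic) plus manual/mandatory terms."""
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    ranked = sorted(freq_table.items(), key=lambda kv: (-kv[1], kv[0]))
    selected = {tok for tok, _ in ranked[:top_k]}
    return Gazetteer(keyword, frozenset(selected | set(manual_additions)))


def default_gazetteers() -> dict[str, Gazetteer]:
    """The authored modifier bank (with misspellings) for each keyword."""
    bank = set(MODIFIERS) | set(MISSPELLINGS.values()) | {"up", "down"}
    return {kw: Gazetteer(kw, frozenset(bank)) for kw in KEYWORDS}


def extract_candidate_sentences(
    sentences: pd.DataFrame, gazetteers: Mapping[str, Gazetteer]
) -> pd.DataFrame:
    """One candidate row per (sentence, construct) with keyword + modifier hit.

    ``sentences`` needs ``sentence_id`` and ``text`` columns; other columns
    are carried through.
    """
    if not gazetteers:
        raise ValueError("at least one gazetteer is required")
    rows = []
    for _, rec in sentences.iterrows():
        tokens = set(tokenize(rec["text"]))
        for construct, gaz in gazetteers.items():
            if gaz.keyword in tokens and tokens & gaz.modifiers:
                row = rec.to_dict()
                row["candidate_construct"] = construct
                rows.append(row)
    if not rows:
        return pd.DataFrame(columns=list(sentences.columns) + ["candidate_construct"])
    return pd.DataFrame(rows)


def write_gazetteer(gaz: Gazetteer, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# keyword: {gaz.keyword}\n")
        for tok in sorted(gaz.modifiers):
            fh.write(tok + "\n")


def read_gazetteer(path) -> Gazetteer:
    keyword = None
    modifiers = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# keyword:"):
                keyword = line.split(":", 1)[1].strip()
            elif line:
                modifiers.add(line)
    if keyword is None:
        raise ValueError("gazetteer file missing '# keyword:' header")
    return Gazetteer(keyword, frozenset(modifiers))
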