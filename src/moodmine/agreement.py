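"""Reference-set sampling and inter-annotator agreement (two raters, binary).

Percent agreement and Cohen's kappa summarise how consistently two
annotators judge the presence of a construct in candidate sentences. Kappa
corrects observed agreement po for the agreement pe expected from the two
raters' marginal label rates: kappa = (po - pe) / (1 - pe).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgreementResult",
    "DegenerateAgreementError",
    "sample_reference_set",
    "percent_agreement",
    "cohens_kappa",
    "simulate_second_annotator",
]


class DegenerateAgreementError(ValueError):
    """Both annotators gave one identical constant label; kappa is undefined."""


@dataclass(frozen=True)
class AgreementResult:
    n: int
    po: float
    pe: float
    kappa: float

    @property
    def percent_agreement(self) -> float:
        return 100.0 * self.po


def sample_reference_set(
    candidates: pd.DataFrame, n: int = 300, seed: int = 0
) -> pd.DataFrame:
    """Simple random sample of candidate sentences without replacement."""
    if n > len(candidates):
        raise ValueError(f"cannot sample {n} sentences from a pool of {len(candidates)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return candidates.iloc[np.sort(idx)].reset_index(drop=True)


def _aligned(a1, a2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(a1, dtype=int)
    y = np.asarray(a2, dtype=int)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("annotations must be equal-length non-empty 1-D vectors")
    return x, y


def percent_agreement(a1, a2) -> float:
    """100 x fraction of identically labeled sentences."""
    x, y = _aligned(a1, a2)
    return 100.0 * float(np.mean(x == y))


def cohens_kappa(a1, a2) -> AgreementResult:
    """Two-class Cohen's kappa with observed/chance agreement components."""
    x, y = _aligned(a1, a2)
    n = len(x)
    po = float(np.mean(x == y))
    pe = float(np.mean(x) * np.mean(y) + np.mean(1 - x) * np.mean(1 - y))
    if pe >= 1.0 - 1e-15:
        raise DegenerateAgreementError(
            "both annotators constant and identical; kappa undefined"
        )
    return AgreementResult(n=n, po=po, pe=pe, kappa=(po - pe) / (1.0 - pe))


def simulate_second_annotator(
    labels, flip_pos: float = 0.05, flip_neg: float = 0.03, seed: int = 0
) -> np.ndarray:
    """Simulated second rater with class-specific disagreement rates."""
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    flip = np.where(y == 1, rng.random(len(y)) < flip_pos, rng.random(len(y)) < flip_neg)
    return np.where(flip, 1 - y, y)
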