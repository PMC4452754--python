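"""Patient-level exposure aggregation.

Combines the three construct classifiers' positive sentences and flags a
patient as having documented mood instability when any positive sentence is
dated within the documentation window (default: day 0 through day 30 after
presentation, inclusive; no lookback).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["LinkageError", "combine_applications", "flag_patients"]


class LinkageError(ValueError):
    """A sentence references a patient absent from the cohort."""


def combine_applications(per_construct: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of positive sentences across constructs.

    Each input frame holds one construct's positive sentences (sentence_id,
    patient_id, date, optionally probability). The same sentence positive for
    several constructs is kept once per construct tag.
    """
    frames = []
    for construct, df in per_construct.items():
        if df is None or len(df) == 0:
            continue
        tagged = df.copy()
        tagged["construct"] = construct
        frames.append(tagged)
    if not frames:
        return pd.DataFrame(columns=["sentence_id", "patient_id", "date", "construct"])
    combined = pd.concat(frames, ignore_index=True)
    return combined.drop_duplicates(subset=["sentence_id", "construct"]).reset_index(
        drop=True
    )


def flag_patients(
    positive_sentences: pd.DataFrame,
    patients: pd.DataFrame,
    window_days: int = 30,
    lookback_days: int = 0,
) -> pd.DataFrame:
    """Binary exposure per patient from dated positive sentences.

    A patient is flagged iff some positive sentence satisfies
    ``-lookback_days <= date - presentation_date <= window_days``.
    Returns patient_id, mi_documented, n_supporting, first_support_date.
    """
    pres = pd.Series(
        np.asarray(patients["presentation_date"], dtype="datetime64[D]").astype(
            "datetime64[ns]"
        ),
        index=patients["patient_id"].to_numpy(),
    )
    out = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "mi_documented": np.zeros(len(patients), dtype=np.int8),
            "n_supporting": np.zeros(len(patients), dtype=int),
            "first_support_date": pd.NaT,
        }
    ).set_index("patient_id")

    if len(positive_sentences):
        unknown = set(positive_sentences["patient_id"]) - set(pres.index)
        if unknown:
            raise LinkageError(
                f"positive sentences reference unknown patient id(s): {sorted(unknown)[:5]}"
            )
        dates = pd.to_datetime(positive_sentences["date"])
        offsets = (dates.to_numpy() - pres.loc[
            positive_sentences["patient_id"]
        ].to_numpy()) / np.timedelta64(1, "D")
        in_window = (offsets >= -lookback_days) & (offsets <= window_days)
        hits = positive_sentences.loc[np.asarray(in_window)]
        if len(hits):
            grp = hits.groupby("patient_id")
            counts = grp.size()
            first = grp["date"].min()
            out.loc[counts.index, "mi_documented"] = 1
            out.loc[counts.index, "n_supporting"] = counts
            out.loc[first.index, "first_support_date"] = pd.to_datetime(first)
    return out.reset_index()
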