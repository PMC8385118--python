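"""Salivary cortisol: circadian correction and AUC-with-respect-to-increase.

Cortisol is sampled four times per participant (arrival s1; immediately,
20 min, and 40 min after the end of the test: s2-s4).  The within-session
circadian decline is removed by subtracting the straight line through
(t1, s1) and (t4, s4) from every sample, which forces the corrected first and
last samples to zero.  Total cortisol released between s2 and s3 is then the
area under the corrected curve with respect to increase,
AUCi = (c3 - c2) * (t3 - t2) / 2 (nmol/L * min; negative when levels fall).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CortisolProfile", "circadian_correct", "auc_increase", "process_cortisol_table"]


@dataclass
class CortisolProfile:
    participant_id: str
    samples: tuple[float, float, float, float]  # nmol/L
    times: tuple[float, float, float, float]  # clock minutes
    group: str = ""

    def __post_init__(self) -> None:
        t = self.times
        if not (t[0] < t[1] < t[2] < t[3]):
            raise ValueError("sampling times must be strictly increasing")
        if any(s < 0 for s in self.samples):
            raise ValueError("cortisol concentrations must be non-negative")


def circadian_correct(profile: CortisolProfile) -> tuple[float, float, float, float]:
    """Subtract the s1-s4 chord: c_i = s_i - [s1 + (s4-s1)(t_i-t1)/(t4-t1)].

    By construction c1 = c4 = 0 exactly, and any linear-in-time trend added to
    the raw profile leaves the corrected values unchanged.
    """
    s, t = profile.samples, profile.times
    if not (np.isfinite(s[0]) and np.isfinite(s[3])):
        raise ValueError(f"participant {profile.participant_id}: s1/s4 missing, cannot correct")
    slope = (s[3] - s[0]) / (t[3] - t[0])
    return tuple(s[i] - (s[0] + slope * (t[i] - t[0])) for i in range(4))


def auc_increase(c2: float, c3: float, t2: float, t3: float) -> float:
    """AUCi over the two post-task corrected samples.

    AUCg = (c2 + c3)/2 * (t3 - t2); the increase term anchors on c2, so
    AUCi = AUCg - c2 * (t3 - t2) = (c3 - c2) * (t3 - t2) / 2.
    """
    if not t3 > t2:
        raise ValueError("t3 must be after t2")
    return (c3 - c2) * (t3 - t2) / 2.0


def process_cortisol_table(df: pd.DataFrame) -> pd.DataFrame:
    """CSV-level pipeline: add corrected values c1..c4 and AUCi per row.

    Expects columns participant_id, group, s1..s4, t1..t4.  Rows with missing
    sampling times get the cohort-mean times substituted (with a warning).
    """
    df = df.copy()
    tcols = ["t1", "t2", "t3", "t4"]
    scols = ["s1", "s2", "s3", "s4"]
    mean_times = df[tcols].mean(axis=0)
    for col in tcols:
        if df[col].isna().any():
            warnings.warn(f"missing sampling times in {col}; cohort means substituted")
            df[col] = df[col].fillna(mean_times[col])
    corrected, aucs = [], []
    for _, row in df.iterrows():
        prof = CortisolProfile(
            participant_id=str(row["participant_id"]),
            samples=tuple(float(row[c]) for c in scols),
            times=tuple(float(row[c]) for c in tcols),
            group=str(row.get("group", "")),
        )
        c = circadian_correct(prof)
        corrected.append(c)
        aucs.append(auc_increase(c[1], c[2], prof.times[1], prof.times[2]))
    for i, name in enumerate(["c1", "c2", "c3", "c4"]):
        df[name] = [c[i] for c in corrected]
    df["AUCi"] = aucs
    return df
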