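"""RNA-Seq prescreen: pick candidate reference genes by abundance and CV.

Transcripts qualify when their mean abundance across samples is high
enough to be quantified reliably (mean raw fragments strictly above
``min_mean``) and their relative variability is low (coefficient of
variation strictly below ``max_cv``). Both inequalities are strict, so
boundary-equal transcripts fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_io import ExpressionTable

__all__ = ["AbundanceStats", "CandidateSet", "abundance_stats", "screen_candidates"]

DEFAULT_MIN_MEAN = 500.0
DEFAULT_MAX_CV = 0.3


@dataclass
class AbundanceStats:
    """Per-transcript mean, sample SD (n-1 denominator) and CV = sd/mean.

    CV is NaN (undefined) for zero-mean transcripts.
    """

    table: pd.DataFrame  # columns: mean, sd, cv

    @classmethod
    def from_summary(cls, mean: pd.Series, sd: pd.Series) -> "AbundanceStats":
        """Build from already-summarised per-transcript mean and SD columns."""
        df = pd.DataFrame({"mean": mean.astype(float), "sd": sd.astype(float)})
        df["cv"] = df["sd"] / df["mean"]
        df.loc[df["mean"] == 0, "cv"] = float("nan")
        return cls(df)


@dataclass
class CandidateSet:
    passing: list[str]
    min_mean: float
    max_cv: float
    report: pd.DataFrame  # columns: mean, sd, cv, passed, reason


def abundance_stats(table: ExpressionTable) -> AbundanceStats:
    """Mean/SD/CV of each transcript's abundance across samples."""
    if table.values.shape[1] < 2:
        raise ValueError("abundance statistics need at least 2 samples (SD undefined)")
    mean = table.values.mean(axis=1)
    sd = table.values.std(axis=1, ddof=1)
    return AbundanceStats.from_summary(mean, sd)


def screen_candidates(
    stats: AbundanceStats,
    min_mean: float = DEFAULT_MIN_MEAN,
    max_cv: float = DEFAULT_MAX_CV,
) -> CandidateSet:
    """Apply the strict mean/CV thresholds and report per-transcript reasons.

    Output rows are ordered by ascending CV (undefined CVs last). A
    zero-mean transcript fails with reason ``zero mean`` rather than
    raising.
    """
    if min_mean <= 0 or max_cv <= 0:
        raise ValueError("thresholds must be positive")
    df = stats.table.copy()
    reasons = []
    passed = []
    for tid, row in df.iterrows():
        why = []
        if row["mean"] == 0:
            why.append("zero mean")
        else:
            if not row["mean"] > min_mean:
                why.append(f"mean <= {min_mean:g}")
            if not row["cv"] < max_cv:
                why.append(f"cv >= {max_cv:g}")
        reasons.append("; ".join(why) if why else "")
        passed.append(not why)
    df["passed"] = passed
    df["reason"] = reasons
    df = df.sort_values("cv", kind="mergesort", na_position="last")
    return CandidateSet(
        passing=list(df.index[df["passed"]]),
        min_mean=float(min_mean),
        max_cv=float(max_cv),
        report=df,
    )
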