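"""BestKeeper descriptive statistics and the comparative ΔCt method.

BestKeeper works on raw Ct, not relative quantities. Each candidate is
summarised by its Ct dispersion (SD and mean absolute deviation, MAD)
and CV%, and correlated against the BestKeeper index — the per-sample
geometric mean of candidate Ct values. Candidates with dispersion below
1 cycle are flagged stable. Both dispersion variants are reported
because the original tool prints MAD while many papers quote SD; the
ranking uses the configured variant (SD by default).

The comparative ΔCt method scores a gene by the mean SD of its pairwise
Ct differences against every other candidate. With all efficiencies
equal to 2 this coincides exactly with geNorm's first-round M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .consensus import rank_genes
from .data_io import CtMatrix, StabilityResult

__all__ = [
    "BestkeeperResult",
    "DeltaCtResult",
    "bestkeeper_descriptives",
    "bestkeeper_index",
    "delta_ct_stability",
]

STABLE_SD_CUTOFF = 1.0


@dataclass
class BestkeeperResult:
    stats: pd.DataFrame             # n, geo_mean, mean, min, max, sd, mad, cv_sd, cv_mad, stable
    dispersion_variant: str = "sd"
    index: pd.Series | None = None  # per-sample BestKeeper index
    correlations: pd.DataFrame | None = None  # per-gene r, p vs index

    def to_stability_result(self) -> StabilityResult:
        scores = self.stats[self.dispersion_variant]
        return StabilityResult(
            algorithm="bestkeeper",
            scores=scores,
            ranks=rank_genes(scores, lower_is_stabler=True),
            metadata={"dispersion_variant": self.dispersion_variant},
        )


def bestkeeper_descriptives(ct: CtMatrix, dispersion_variant: str = "sd") -> BestkeeperResult:
    """Per-gene Ct descriptives and the dispersion-based stable flag."""
    if dispersion_variant not in ("sd", "mad"):
        raise ValueError("dispersion_variant must be 'sd' or 'mad'")
    vals = ct.values
    if vals.shape[1] < 2:
        raise ValueError("BestKeeper needs at least 2 samples")
    if (vals.to_numpy(dtype=float) <= 0)[np.isfinite(vals.to_numpy(dtype=float))].any():
        raise ValueError("nonpositive Ct: geometric mean undefined")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    mad = (vals.sub(mean, axis=0)).abs().mean(axis=1)
    stats_df = pd.DataFrame(
        {
            "n": vals.notna().sum(axis=1),
            "geo_mean": np.exp(np.log(vals).mean(axis=1)),
            "mean": mean,
            "min": vals.min(axis=1),
            "max": vals.max(axis=1),
            "sd": sd,
            "mad": mad,
            "cv_sd": sd / mean * 100.0,
            "cv_mad": mad / mean * 100.0,
        }
    )
    stats_df["stable"] = stats_df[dispersion_variant] < STABLE_SD_CUTOFF
    return BestkeeperResult(stats_df, dispersion_variant)


def bestkeeper_index(ct: CtMatrix, genes: list[str] | None = None) -> BestkeeperResult:
    """BestKeeper index and per-gene Pearson correlation against it.

    The index is the per-sample geometric mean of the subset's Ct values.
    A zero-variance gene has undefined r, reported as NaN (never 0); its
    p-value is NaN too.
    """
    result = bestkeeper_descriptives(ct)
    genes = list(ct.values.index) if genes is None else list(genes)
    if len(genes) < 2:
        raise ValueError("BestKeeper index needs at least 2 genes")
    sub = ct.values.loc[genes]
    index = pd.Series(
        np.exp(np.log(sub).mean(axis=0, skipna=False)), index=sub.columns, name="index"
    )
    rows = {}
    for g in ct.values.index:
        row = ct.values.loc[g]
        ok = row.notna() & index.notna()
        x, y = row[ok].to_numpy(), index[ok].to_numpy()
        if len(x) < 3 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
            rows[g] = (np.nan, np.nan)
            continue
        r, p = sps.pearsonr(x, y)
        rows[g] = (float(r), float(p))
    result.index = index
    result.correlations = pd.DataFrame(rows, index=["r", "p"]).T
    return result


@dataclass
class DeltaCtResult:
    scores: pd.Series          # per-gene mean pairwise SD of dCt
    pairwise_sd: pd.DataFrame  # symmetric, zero diagonal

    def to_stability_result(self) -> StabilityResult:
        return StabilityResult(
            algorithm="delta_ct",
            scores=self.scores,
            ranks=rank_genes(self.scores, lower_is_stabler=True),
        )


def delta_ct_stability(ct: CtMatrix) -> DeltaCtResult:
    """Mean pairwise SD of Ct differences; lower = more stable."""
    genes = list(ct.values.index)
    if len(genes) < 3:
        raise ValueError("comparative dCt needs at least 3 genes")
    vals = ct.values.to_numpy(dtype=float)
    n_genes = len(genes)
    mat = np.zeros((n_genes, n_genes))
    incomplete = False
    for a in range(n_genes):
        for b in range(a + 1, n_genes):
            diff = vals[a] - vals[b]
            diff = diff[np.isfinite(diff)]
            if len(diff) < 2:
                mat[a, b] = mat[b, a] = np.nan
                incomplete = True
                continue
            mat[a, b] = mat[b, a] = diff.std(ddof=1)
    if incomplete:
        warnings.warn("some gene pairs share <2 samples; their SDs are excluded", stacklevel=2)
    pair_df = pd.DataFrame(mat, index=genes, columns=genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        off_diag = pair_df.where(~np.eye(n_genes, dtype=bool))
        scores = off_diag.mean(axis=1, skipna=True)
    scores.name = "delta_ct"
    return DeltaCtResult(scores, pair_df)
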