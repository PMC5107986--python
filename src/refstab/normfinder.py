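"""Model-based stability estimation (NormFinder-style).

Works on log2 relative quantities. Each sample is first centred by its
across-gene mean, which removes sample loading artifacts exactly. For a
grouped design the estimator then combines, per gene:

* an intragroup variance, bias-adjusted by subtracting the average
  variance of the other genes scaled by 1/(G-1) and floored at a small
  positive value, and
* an intergroup difference d (the gene's deviation of group means from
  its overall mean), shrunk towards zero by the ratio of the across-gene
  variance of d to its total variance.

The stability value is rho_g = mean over groups of
|d_shrunk| + sqrt(sigma2_adj / n_group); lower is more stable. With a
single group all d terms are zero and rho reduces to the adjusted
intragroup SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import rank_genes
from .data_io import SampleMetadata, StabilityResult
from .qpcr_core import QuantityMatrix

__all__ = ["NormfinderResult", "normfinder_stability", "normfinder_single_group"]

VARIANCE_FLOOR = 1e-8


@dataclass
class NormfinderResult:
    stability: pd.Series               # rho per gene
    group_variances: pd.DataFrame      # genes x groups, bias-adjusted sigma^2
    group_differences: pd.DataFrame    # genes x groups, shrunken d
    grouping: str

    def to_stability_result(self) -> StabilityResult:
        return StabilityResult(
            algorithm="normfinder",
            scores=self.stability,
            ranks=rank_genes(self.stability, lower_is_stabler=True),
            metadata={"grouping": self.grouping},
        )


def _centered_log_matrix(q: QuantityMatrix) -> pd.DataFrame:
    """log2 quantities centred per sample; samples with any missing gene dropped."""
    x = np.log2(q.values)
    complete = x.notna().all(axis=0)
    x = x.loc[:, complete]
    return x - x.mean(axis=0)


def normfinder_stability(
    q: QuantityMatrix,
    meta: SampleMetadata,
    grouping: str = "treatment",
) -> NormfinderResult:
    """Combined intra/intergroup stability value per gene; lower = stabler."""
    z = _centered_log_matrix(q)
    genes = list(z.index)
    n_genes = len(genes)
    if n_genes < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    labels = meta.groups(grouping).reindex(z.columns)
    if labels.isna().any():
        missing = list(z.columns[labels.isna()])
        raise ValueError(f"samples absent from metadata: {missing}")
    group_names = sorted(labels.unique())

    sigma2 = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    zbar = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    n_per_group = {}
    for grp in group_names:
        cols = z.columns[labels == grp]
        if len(cols) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
        sub = z[cols]
        n_per_group[grp] = len(cols)
        zbar[grp] = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        # bias adjustment: per-sample centering leaks 1/(G-1) of the other
        # genes' noise into each residual; subtract their mean variance scaled
        adj = s2 - (s2.sum() - s2) / (n_genes - 1) ** 2
        sigma2[grp] = np.maximum(adj, VARIANCE_FLOOR)

    # intergroup differences, centred per gene over groups
    d = zbar.sub(zbar.mean(axis=1), axis=0)
    d_shrunk = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    for grp in group_names:
        gamma2 = float(d[grp].var(ddof=1)) if n_genes > 1 else 0.0
        denom = gamma2 + sigma2[grp] / n_per_group[grp]
        shrink = np.where(denom > 0, gamma2 / denom, 0.0)
        d_shrunk[grp] = d[grp] * shrink

    per_group = d_shrunk.abs() + np.sqrt(
        sigma2 / pd.Series(n_per_group).reindex(group_names)
    )
    rho = per_group.mean(axis=1)
    rho.name = "stability"
    return NormfinderResult(rho, sigma2, d_shrunk, grouping)


def normfinder_single_group(q: QuantityMatrix) -> NormfinderResult:
    """Single-condition fallback: rho is the adjusted intragroup SD."""
    z = _centered_log_matrix(q)
    genes = list(z.index)
    n_genes = len(genes)
    if n_genes < 2:
        raise ValueError("NormFinder needs at least 2 genes")
    if z.shape[1] < 3:
        raise ValueError("single-group NormFinder needs at least 3 samples")
    s2 = z.var(axis=1, ddof=1)
    adj = s2 - (s2.sum() - s2) / (n_genes - 1) ** 2
    sigma2 = np.maximum(adj, VARIANCE_FLOOR)
    rho = pd.Series(np.sqrt(sigma2), index=genes, name="stability")
    frame = pd.DataFrame({"all": sigma2}, index=genes)
    zeros = pd.DataFrame({"all": np.zeros(n_genes)}, index=genes)
    return NormfinderResult(rho, frame, zeros, grouping="(single group)")
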