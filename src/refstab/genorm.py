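"""geNorm: expression-stability measure M and pairwise variation V(n/n+1).

For genes g, k the pairwise variation V_gk is the sample SD of the
log2-ratio of their relative quantities across samples; M_g is the mean
of V_gk over all other candidates. Ranking proceeds by iteratively
excluding the gene with the highest M until two genes remain — these form
the recommended pair and share one M (their mutual V). The V(n/n+1)
series compares normalization factors built from the n and n+1 most
stable genes; the smallest n with V below the threshold (default 0.15)
is the recommended number of reference genes. Genes whose full-set M
exceeds 1.5 are flagged as unusable.

Missing samples are dropped pairwise (per V_gk), not listwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import StabilityResult
from .qpcr_core import QuantityMatrix
from .consensus import rank_genes

__all__ = [
    "GenormResult",
    "pairwise_gene_variation",
    "m_values",
    "genorm_ranking",
    "normalization_factor",
    "pairwise_v",
]

M_CUTOFF = 1.5
V_THRESHOLD = 0.15


def pairwise_gene_variation(q: QuantityMatrix, g: str, k: str) -> float:
    """Sample SD (n-1) of log2(Q_g / Q_k) over common non-missing samples."""
    if g == k:
        raise ValueError("pairwise variation needs two distinct genes")
    ratio = np.log2(q.values.loc[g]) - np.log2(q.values.loc[k])
    ratio = ratio.dropna()
    if len(ratio) < 2:
        raise ValueError(f"genes {g!r} and {k!r} share fewer than 2 samples")
    return float(ratio.std(ddof=1))


def m_values(q: QuantityMatrix, genes: list[str] | None = None) -> pd.Series:
    """M_g = mean pairwise variation of g against all other genes in the set."""
    genes = list(q.values.index) if genes is None else list(genes)
    if len(genes) < 2:
        raise ValueError("M values need at least 2 genes")
    log_q = np.log2(q.values.loc[genes]).to_numpy(dtype=float)
    n_genes = len(genes)
    v = np.zeros((n_genes, n_genes))
    for a in range(n_genes):
        for b in range(a + 1, n_genes):
            ratio = log_q[a] - log_q[b]
            ratio = ratio[np.isfinite(ratio)]
            if len(ratio) < 2:
                raise ValueError(f"genes {genes[a]!r}, {genes[b]!r}: <2 common samples")
            v[a, b] = v[b, a] = ratio.std(ddof=1)
    m = v.sum(axis=1) / (n_genes - 1)
    return pd.Series(m, index=genes, name="M")


@dataclass
class GenormResult:
    """Iterative-exclusion ranking with full M trace and V series."""

    final_m: pd.Series            # per-gene M at its exclusion step (pair shares one M)
    exclusion_order: list[str]    # first excluded (least stable) ... best pair last
    best_pair: tuple[str, str]
    m_trace: list[pd.Series]      # M values at every round, full set first
    tie_breaks: list[str] = field(default_factory=list)
    unusable: list[str] = field(default_factory=list)  # full-set M > cutoff
    v_series: pd.Series | None = None
    optimal_n: int | None = None
    threshold_met: bool = True

    @property
    def ranking(self) -> list[str]:
        """Most to least stable (best pair first, alphabetical within pair)."""
        return list(reversed(self.exclusion_order))

    def to_stability_result(self) -> StabilityResult:
        return StabilityResult(
            algorithm="genorm",
            scores=self.final_m,
            ranks=rank_genes(self.final_m, lower_is_stabler=True),
            metadata={
                "best_pair": list(self.best_pair),
                "tie_breaks": list(self.tie_breaks),
                "unusable": list(self.unusable),
            },
        )


def genorm_ranking(q: QuantityMatrix, m_cutoff: float = M_CUTOFF) -> GenormResult:
    """Rank genes by iterative exclusion of the highest-M candidate.

    Ties at the maximum M are broken by excluding the lexicographically
    last gene id (recorded in ``tie_breaks``). The surviving two genes are
    reported as the best pair with their mutual pairwise variation as a
    shared M.
    """
    genes = list(q.values.index)
    if len(genes) < 3:
        raise ValueError("geNorm ranking needs at least 3 genes")
    full_m = m_values(q, genes)
    unusable = list(full_m.index[full_m > m_cutoff])

    remaining = list(genes)
    exclusion_order: list[str] = []
    final_m: dict[str, float] = {}
    m_trace: list[pd.Series] = []
    tie_breaks: list[str] = []
    while len(remaining) > 2:
        m = m_values(q, remaining)
        m_trace.append(m)
        worst_m = m.max()
        at_max = sorted(m.index[m == worst_m])
        worst = at_max[-1]
        if len(at_max) > 1:
            tie_breaks.append(worst)
        final_m[worst] = float(m[worst])
        exclusion_order.append(worst)
        remaining.remove(worst)

    pair = tuple(sorted(remaining))
    pair_m = pairwise_gene_variation(q, pair[0], pair[1])
    m_trace.append(pd.Series(pair_m, index=list(pair), name="M"))
    for g in pair:
        final_m[g] = pair_m
        exclusion_order.append(g)

    return GenormResult(
        final_m=pd.Series(final_m).reindex(genes),
        exclusion_order=exclusion_order,
        best_pair=pair,
        m_trace=m_trace,
        tie_breaks=tie_breaks,
        unusable=unusable,
    )


def normalization_factor(q: QuantityMatrix, genes: list[str]) -> pd.Series:
    """Per-sample geometric mean of the subset's quantities.

    A sample missing any gene of the subset gets a missing NF.
    """
    if not genes:
        raise ValueError("normalization factor needs a non-empty gene subset")
    log_q = np.log2(q.values.loc[list(genes)])
    return pd.Series(
        np.power(2.0, log_q.mean(axis=0, skipna=False)),
        index=q.values.columns,
        name="NF",
    )


def pairwise_v(
    q: QuantityMatrix,
    ranking: GenormResult,
    threshold: float = V_THRESHOLD,
) -> GenormResult:
    """V(n/n+1) series over the geNorm-ranked nested gene sets.

    V(n/n+1) is the sample SD of log2(NF_n / NF_{n+1}), where NF_n uses
    the n most stable genes. ``optimal_n`` is the smallest n with
    V < threshold; if the threshold is never met, optimal_n = G and
    ``threshold_met`` is False. The result is returned with the series
    attached.
    """
    order = ranking.ranking
    n_genes = len(order)
    if n_genes < 3:
        raise ValueError("V series needs at least 3 genes")
    v = {}
    for n in range(2, n_genes):
        nf_n = np.log2(normalization_factor(q, order[:n]))
        nf_n1 = np.log2(normalization_factor(q, order[: n + 1]))
        v[f"V{n}/{n + 1}"] = float((nf_n - nf_n1).std(ddof=1))
    series = pd.Series(v, name="V")
    below = [n for n, val in zip(range(2, n_genes), series.to_numpy()) if val < threshold]
    if below:
        ranking.optimal_n = below[0]
        ranking.threshold_met = True
    else:
        ranking.optimal_n = n_genes
        ranking.threshold_met = False
    ranking.v_series = series
    return ranking
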