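"""Consensus ranking across stability algorithms.

Each algorithm contributes a per-gene rank (1 = most stable, ties share
the mean of their positions). A gene's comprehensive value is the
geometric mean of its ranks; the final ordering sorts this value
ascending with gene-id tie-break. The comprehensive value lives in
[1, G]: exactly 1 iff ranked first everywhere, exactly G iff ranked last
everywhere. Agreement sets intersect the top-k (or bottom-k) genes
across algorithms, mirroring the Venn-diagram comparison of methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import StabilityResult

__all__ = ["ConsensusResult", "rank_genes", "comprehensive_rank", "method_agreement"]


def rank_genes(scores: pd.Series, lower_is_stabler: bool = True) -> pd.Series:
    """Average ranks of stability scores; rank 1 is the most stable gene.

    Missing scores rank after every finite score (warned upstream).
    """
    vals = scores.to_numpy(dtype=float)
    keyed = vals if lower_is_stabler else -vals
    keyed = np.where(np.isnan(keyed), np.inf, keyed)
    return pd.Series(rankdata(keyed, method="average"), index=scores.index, name="rank")


@dataclass
class ConsensusResult:
    ranks_by_method: pd.DataFrame      # genes x algorithms
    comprehensive_value: pd.Series     # geometric mean of ranks
    final_rank: pd.Series              # rank of the comprehensive value
    final_order: list[str]             # most to least stable, id tie-break

    def to_dict(self) -> dict:
        return {
            "ranks_by_method": {
                alg: {str(g): float(v) for g, v in col.items()}
                for alg, col in self.ranks_by_method.items()
            },
            "comprehensive_value": {str(g): float(v) for g, v in self.comprehensive_value.items()},
            "final_order": [str(g) for g in self.final_order],
        }


def comprehensive_rank(rank_lists: dict[str, pd.Series] | list[StabilityResult]) -> ConsensusResult:
    """Geometric-mean aggregation of two or more per-gene rank vectors."""
    if isinstance(rank_lists, list):
        rank_lists = {res.algorithm: res.ranks for res in rank_lists}
    if len(rank_lists) < 2:
        raise ValueError("consensus needs at least 2 rank lists")
    names = list(rank_lists)
    base = set(rank_lists[names[0]].index)
    for name in names[1:]:
        other = set(rank_lists[name].index)
        if other != base:
            diff = sorted(base.symmetric_difference(other))
            raise ValueError(f"gene sets differ between {names[0]!r} and {name!r}: {diff}")
    index = rank_lists[names[0]].index
    ranks = pd.DataFrame({name: rank_lists[name].reindex(index) for name in names})
    value = pd.Series(
        np.exp(np.log(ranks.to_numpy(dtype=float)).mean(axis=1)),
        index=index,
        name="comprehensive",
    )
    order_df = pd.DataFrame({"value": value, "gene": index.astype(str)})
    order_df.index.name = None
    final_order = list(order_df.sort_values(["value", "gene"]).index)
    final_rank = rank_genes(value, lower_is_stabler=True)
    return ConsensusResult(ranks, value, final_rank, final_order)


def method_agreement(
    orderings: dict[str, list[str]], k: int
) -> tuple[set[str], set[str]]:
    """Intersections of each algorithm's k most and k least stable genes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for name, order in orderings.items():
        if k > len(order):
            raise ValueError(f"k={k} exceeds gene count for {name!r}")
    tops = [set(order[:k]) for order in orderings.values()]
    bottoms = [set(order[-k:]) for order in orderings.values()]
    return set.intersection(*tops), set.intersection(*bottoms)
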