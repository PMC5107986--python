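"""Glue: run the four stability algorithms and the consensus in one call."""

from __future__ import annotations

from .consensus import ConsensusResult, comprehensive_rank, method_agreement
from .data_io import CtMatrix, SampleMetadata, StabilityResult
from .descriptive_stability import bestkeeper_index, delta_ct_stability
from .genorm import genorm_ranking, pairwise_v
from .normfinder import normfinder_single_group, normfinder_stability
from .qpcr_core import relative_quantities

__all__ = ["evaluate_stability", "ALGORITHMS"]

ALGORITHMS = ("genorm", "normfinder", "bestkeeper", "delta_ct")


def evaluate_stability(
    ct: CtMatrix,
    meta: SampleMetadata | None = None,
    grouping: str = "treatment",
    algorithms: tuple[str, ...] = ALGORITHMS,
    samples: list[str] | None = None,
) -> tuple[list[StabilityResult], ConsensusResult, dict]:
    """Run the requested algorithms on (a subset of) a Ct matrix.

    Returns the per-algorithm results, the geometric-mean consensus over
    their ranks, and a detail dict with each algorithm's native output
    (geNorm V series and best pair included).
    """
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
    if len(algorithms) < 2:
        raise ValueError("consensus needs at least 2 algorithms")
    if samples is not None:
        ct = ct.subset_samples(samples)
    q = relative_quantities(ct)

    results: list[StabilityResult] = []
    detail: dict = {}
    if "genorm" in algorithms:
        gres = pairwise_v(q, genorm_ranking(q))
        results.append(gres.to_stability_result())
        detail["genorm"] = gres
    if "normfinder" in algorithms:
        if meta is not None and meta.groups(grouping).reindex(q.values.columns).nunique() > 1:
            nres = normfinder_stability(q, meta, grouping)
        else:
            nres = normfinder_single_group(q)
        results.append(nres.to_stability_result())
        detail["normfinder"] = nres
    if "bestkeeper" in algorithms:
        bres = bestkeeper_index(ct)
        results.append(bres.to_stability_result())
        detail["bestkeeper"] = bres
    if "delta_ct" in algorithms:
        dres = delta_ct_stability(ct)
        results.append(dres.to_stability_result())
        detail["delta_ct"] = dres

    consensus = comprehensive_rank(results)
    detail["agreement_top4"], detail["agreement_bottom4"] = method_agreement(
        {r.algorithm: r.ordering() for r in results}, k=min(4, len(ct.gene_ids))
    )
    return results, consensus, detail
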