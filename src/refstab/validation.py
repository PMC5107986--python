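"""Target-gene normalization validation.

Re-evaluates chosen reference genes by normalizing a target gene against
alternative reference sets and testing whether the choice of normalizer
changes the estimated expression. Normalized expression follows the
efficiency-corrected ratio model: with a calibrator sample,

    ratio_i = E_t**(Ct_t,cal - Ct_t,i) / geomean_r E_r**(Ct_r,cal - Ct_r,i)

so the calibrator's ratio is 1. Without a calibrator the min-Ct-referenced
quantity scale is used and values are relative (arbitrary per-set scale).
Differences between reference sets are tested per sample group with a
one-way ANOVA on log2 normalized expression; when no calibrator anchors
the scale, each set's series is first rescaled to geometric mean 1 so
that only profile differences — never the arbitrary scale — can flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import CtMatrix, SampleMetadata

__all__ = [
    "NormalizedExpression",
    "normalized_expression",
    "one_way_anova",
    "compare_normalizers",
]

ALPHA = 0.01


@dataclass
class NormalizedExpression:
    values: pd.Series                # per-sample relative expression of the target
    target: str
    references: tuple[str, ...]
    calibrator: str | None
    replicate_values: pd.DataFrame | None = None  # samples x replicates


def _replicate_ratios(
    ct: CtMatrix, target: str, refs: list[str], anchor_t: float, anchor_r: pd.Series
) -> pd.DataFrame | None:
    """Per-technical-replicate ratios (samples x replicates), if available."""
    if ct.replicates is None:
        return None
    genes = ct.gene_ids
    eff = ct.efficiency_vector()
    t_idx = genes.index(target)
    r_idx = [genes.index(r) for r in refs]
    reps = ct.replicates  # genes x samples x replicates
    e_t = float(eff[target])
    num = np.power(e_t, anchor_t - reps[t_idx])  # samples x reps
    log_den = np.zeros_like(num)
    for j, r in zip(r_idx, refs):
        e_r = float(eff[r])
        log_den += (float(anchor_r[r]) - reps[j]) * np.log2(e_r)
    den = np.power(2.0, log_den / len(refs))
    return pd.DataFrame(num / den, index=ct.sample_ids)


def normalized_expression(
    ct: CtMatrix,
    target: str,
    refs: list[str],
    calibrator: str | None = None,
    use_replicates: bool = False,
) -> NormalizedExpression:
    """Efficiency-corrected expression of ``target`` relative to ``refs``.

    ``calibrator`` names a sample whose ratio is fixed at 1; without one,
    each gene is referenced to its own minimum Ct and values are relative.
    A sample missing the target or any reference Ct gets a missing ratio.
    """
    refs = list(refs)
    if target in refs:
        raise ValueError(f"target {target!r} cannot be one of its references")
    for g in [target, *refs]:
        if g not in ct.values.index:
            raise ValueError(f"gene {g!r} not in Ct matrix")
    eff = ct.efficiency_vector()
    if calibrator is not None:
        if calibrator not in ct.values.columns:
            raise ValueError(f"calibrator sample {calibrator!r} not in Ct matrix")
        anchor_t = float(ct.values.loc[target, calibrator])
        anchor_r = ct.values.loc[refs, calibrator]
    else:
        anchor_t = float(ct.values.loc[target].min())
        anchor_r = ct.values.loc[refs].min(axis=1)

    num = np.power(float(eff[target]), anchor_t - ct.values.loc[target])
    log_den = pd.Series(0.0, index=ct.values.columns)
    for r in refs:
        log_den = log_den + (float(anchor_r[r]) - ct.values.loc[r]) * np.log2(float(eff[r]))
    den = np.power(2.0, log_den / len(refs))
    ratios = num / den
    ratios.name = f"{target}|{'+'.join(refs)}"
    reps = (
        _replicate_ratios(ct, target, refs, anchor_t, anchor_r) if use_replicates else None
    )
    return NormalizedExpression(ratios, target, tuple(refs), calibrator, reps)


def one_way_anova(groups: list[np.ndarray] | dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Identical groups give F = 0, p = 1 (zero between-group variance).
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("every ANOVA group needs at least 2 values")
    grand = np.concatenate(arrays)
    if np.allclose(grand, grand[0]):
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    if np.isnan(f):  # zero within-group variance with equal means
        return 0.0, 1.0
    return float(f), float(p)


@dataclass
class NormalizerComparison:
    expression: pd.DataFrame        # samples x reference sets (log2 scale)
    anova: pd.DataFrame             # per-group F, p, flagged
    alpha: float
    flagged_groups: list[str]


def compare_normalizers(
    ct: CtMatrix,
    target: str,
    reference_sets: dict[str, list[str]],
    meta: SampleMetadata,
    grouping: str = "organ",
    calibrator: str | None = None,
    alpha: float = ALPHA,
) -> NormalizerComparison:
    """Test whether normalizer choice changes the target's estimate.

    For every sample group, a one-way ANOVA compares the log2 normalized
    expression of the target across reference sets. With technical
    replicates attached, replicate-level ratios supply the within-group
    degrees of freedom; otherwise sample-level values within the group do.
    Identical reference sets can never flag.
    """
    if len(reference_sets) < 2:
        raise ValueError("need at least 2 reference sets to compare")
    norm = {
        name: normalized_expression(ct, target, refs, calibrator, use_replicates=True)
        for name, refs in reference_sets.items()
    }

    def _anchored_log2(ne: NormalizedExpression, frame: pd.DataFrame | pd.Series):
        vals = np.log2(frame)
        if calibrator is None:
            # remove arbitrary per-set scale from min-Ct referencing
            center = np.log2(ne.values).mean()
            vals = vals - center
        return vals

    expr = pd.DataFrame({name: _anchored_log2(ne, ne.values) for name, ne in norm.items()})

    labels = meta.groups(grouping).reindex(ct.values.columns)
    rows = {}
    for grp in sorted(labels.dropna().unique()):
        samples = list(labels.index[labels == grp])
        groups = []
        for name, ne in norm.items():
            if ne.replicate_values is not None:
                vals = _anchored_log2(ne, ne.replicate_values).loc[samples].to_numpy().ravel()
            else:
                vals = expr.loc[samples, name].to_numpy()
            vals = vals[np.isfinite(vals)]
            groups.append(vals)
        if any(len(g) < 2 for g in groups):
            rows[grp] = (np.nan, np.nan, False)
            continue
        f, p = one_way_anova(groups)
        rows[grp] = (f, p, bool(p < alpha))
    anova = pd.DataFrame(rows, index=["F", "p", "flagged"]).T
    anova["flagged"] = anova["flagged"].astype(bool)
    flagged = list(anova.index[anova["flagged"]])
    return NormalizerComparison(expr, anova, alpha, flagged)
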