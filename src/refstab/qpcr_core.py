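"""qPCR primitives: standard-curve efficiency, Ct descriptives, quantities.

The amplification efficiency E is the per-cycle amplification factor
(E = 2 for perfect doubling). It is estimated from the slope of the
standard curve Ct ~ log10(template amount):

    E_percent = (10**(-1/slope) - 1) * 100

Relative quantities follow the geNorm input convention: each gene's Ct
row is referenced to its own minimum (the most-expressed sample), so
Q = E**(minCt - Ct) lies in (0, 1] with max 1. Referencing to the mean
Ct instead would only rescale Q per gene, which every downstream
log-ratio statistic cancels out (a tested property).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CtMatrix

__all__ = [
    "DilutionSeries",
    "StandardCurveFit",
    "QuantityMatrix",
    "fit_standard_curve",
    "efficiency_from_slope",
    "ct_descriptives",
    "relative_quantities",
]

#: Fitted efficiencies beyond this percentage trigger a plausibility warning.
PLAUSIBLE_EFFICIENCY_MAX = 110.0


@dataclass
class DilutionSeries:
    """Standard-curve points for one gene: log10 template amount vs Ct."""

    gene: str
    log10_amount: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.log10_amount = np.asarray(self.log10_amount, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.log10_amount.shape != self.ct.shape:
            raise ValueError("log10_amount and ct must be the same length")
        if len(np.unique(self.log10_amount)) < 3:
            raise ValueError("need at least 3 distinct dilution levels")
        if not np.all(np.isfinite(self.ct)):
            raise ValueError("non-finite Ct in dilution series")
        # Ct should rise as template falls; warn, don't fail (noise can flip pairs)
        order = np.argsort(self.log10_amount)
        if np.any(np.diff(self.ct[order]) > 0) and np.corrcoef(self.log10_amount, self.ct)[0, 1] > 0:
            warnings.warn(f"{self.gene}: Ct does not decrease with template amount", stacklevel=2)


@dataclass
class StandardCurveFit:
    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    valid: bool = True

    @property
    def efficiency_fold(self) -> float:
        return 1.0 + self.efficiency_percent / 100.0


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency from a standard-curve slope.

    Strictly decreasing in |slope|; a slope of -3.3219 (= -1/log10(2))
    gives exactly 100%. Slopes >= 0 are physically meaningless.
    """
    if not slope < 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    if eff > PLAUSIBLE_EFFICIENCY_MAX:
        warnings.warn(
            f"implausible amplification efficiency {eff:.1f}% (slope {slope:g})",
            stacklevel=2,
        )
    return eff


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """OLS fit of Ct on log10(amount); efficiency from the slope.

    R^2 is the squared Pearson correlation of fitted vs observed Ct.
    Replicate points at the same level are fitted as-is; with balanced
    replication this equals fitting the per-level means.
    """
    x, y = series.log10_amount, series.ct
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    if np.allclose(y, y[0]):
        r2 = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    if slope >= 0:
        return StandardCurveFit(series.gene, float(slope), float(intercept), r2,
                                float("nan"), valid=False)
    return StandardCurveFit(
        series.gene, float(slope), float(intercept), r2, efficiency_from_slope(slope)
    )


def ct_descriptives(ct: CtMatrix) -> pd.DataFrame:
    """Per-gene mean, SD (n-1) and CV of Ct over non-missing samples.

    Genes with fewer than 2 observed samples are excluded with a warning.
    """
    vals = ct.values
    n_obs = vals.notna().sum(axis=1)
    dropped = list(vals.index[n_obs < 2])
    if dropped:
        warnings.warn(f"excluded genes with <2 observed Ct values: {dropped}", stacklevel=2)
    keep = vals.loc[n_obs >= 2]
    out = pd.DataFrame(
        {
            "n": keep.notna().sum(axis=1),
            "mean": keep.mean(axis=1),
            "sd": keep.std(axis=1, ddof=1),
        }
    )
    out["cv"] = out["sd"] / out["mean"]
    return out


@dataclass
class QuantityMatrix:
    """Relative quantities Q in (0, 1], genes x samples; max per gene is 1."""

    values: pd.DataFrame
    reference_ct: pd.Series  # per-gene min Ct used for scaling
    efficiencies: pd.Series

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def subset_genes(self, genes) -> "QuantityMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return QuantityMatrix(
            self.values.loc[keep], self.reference_ct.loc[keep], self.efficiencies.loc[keep]
        )

    def subset_samples(self, samples) -> "QuantityMatrix":
        keep = [s for s in self.values.columns if s in set(samples)]
        return QuantityMatrix(self.values[keep], self.reference_ct, self.efficiencies)


def relative_quantities(ct: CtMatrix, default_efficiency: float = 2.0) -> QuantityMatrix:
    """Efficiency-corrected relative quantities, min-Ct referenced.

    Q_g(sample i) = E_g ** (minCt_g - Ct_gi); the most-expressed sample of
    each gene gets Q = 1. Missing Ct propagates to missing Q. When no
    efficiencies are attached, E = 2 (100%) is assumed with a warning.
    """
    if ct.efficiencies is None:
        warnings.warn(
            f"no amplification efficiencies attached; assuming E = {default_efficiency}",
            stacklevel=2,
        )
    eff = ct.efficiency_vector(default_efficiency)
    min_ct = ct.values.min(axis=1)
    delta = ct.values.rsub(min_ct, axis=0)  # minCt - Ct <= 0
    q = pd.DataFrame(
        np.power(eff.to_numpy()[:, None], delta.to_numpy(dtype=float)),
        index=ct.values.index,
        columns=ct.values.columns,
    )
    return QuantityMatrix(q, min_ct, eff)
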