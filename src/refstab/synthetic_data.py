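"""Synthetic qPCR and RNA-Seq data with known ground truth.

The generator emulates the measured inputs of a reference-gene study on
a 14-sample design: leaves and fruits at developmental stages 3/4/7 and
flowers at the flowering stage, each under control and drought
conditions. The measurement model on the log2-expression scale is

    x_gi = m_g + delta_{g, group(i)} + L_i + eps_gi

with sample loading factors L_i ~ N(0, tau^2) and biological noise
eps_gi ~ N(0, sigma_g^2). Quantification cycles follow from the per-gene
amplification efficiency E_g:

    Ct_gi = a_g - x_gi * ln(2) / ln(E_g)

so one log2 unit of expression moves Ct by one cycle when E = 2.
Technical replicates add independent N(0, tech_sd^2) cycles on top.
Fragment counts for the prescreen are negative binomial with mean
mu_g * 2**(delta + L) and per-gene dispersion (variance mu + d*mu^2;
d = 0 degenerates to Poisson).

One master seed spawns independent substreams per stage (loading,
biological noise, technical replicates, counts) so stages can be varied
independently without perturbing one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CtMatrix, SampleMetadata
from .data_io import ExpressionTable
from .qpcr_core import DilutionSeries

__all__ = [
    "SampleCell",
    "SimulationConfig",
    "SimulationTruth",
    "default_design",
    "simulate_ct_dataset",
    "simulate_fragment_counts",
    "simulate_dilution_series",
]


@dataclass(frozen=True)
class SampleCell:
    sample_id: str
    organ: str
    stage: str
    treatment: str


def default_design() -> list[SampleCell]:
    """The 14-sample design: leaf/fruit x stages 3/4/7, flower x stage 2,
    each under control (C) and drought (D)."""
    cells = []
    for treat, code in (("control", "C"), ("drought", "D")):
        for stage in ("3", "4", "7"):
            cells.append(SampleCell(f"{code}-L{stage}", "leaf", stage, treat))
        cells.append(SampleCell(f"{code}-F", "flower", "2", treat))
        for stage in ("3", "4", "7"):
            cells.append(SampleCell(f"{code}-G{stage}", "fruit", stage, treat))
    return cells


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated study.

    ``group_effects`` maps gene -> group label -> shift in log2 units; the
    grouping axis is ``effect_grouping`` (default treatment). Baseline Ct
    intercepts sit in the observed qPCR range (high teens to mid twenties).
    """

    genes: list[str]
    noise_sd: dict[str, float]                      # sigma_g, log2 units
    baseline_ct: dict[str, float] | None = None     # a_g, cycles
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    effect_grouping: str = "treatment"
    design: list[SampleCell] = field(default_factory=default_design)
    loading_sd: float = 0.2                         # tau, log2 units
    efficiencies: dict[str, float] | None = None    # E_g, fold scale
    tech_rep_sd: float = 0.1                        # cycles
    n_tech_reps: int = 3
    fragment_mean: dict[str, float] | None = None   # mu_g
    fragment_dispersion: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in config")
        if len(self.design) < 2:
            raise ValueError("design needs at least 2 samples")
        if self.loading_sd < 0 or self.tech_rep_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        for g in self.genes:
            if self.noise_sd.get(g, -1.0) < 0:
                raise ValueError(f"noise SD missing or negative for gene {g!r}")
        if self.baseline_ct is None:
            # spread intercepts across the observed Ct range, deterministic
            self.baseline_ct = {
                g: 18.0 + 7.0 * i / max(len(self.genes) - 1, 1)
                for i, g in enumerate(self.genes)
            }
        if self.efficiencies is None:
            self.efficiencies = {g: 2.0 for g in self.genes}
        for g, e in self.efficiencies.items():
            if not (1.0 < e <= 2.2):
                raise ValueError(f"efficiency for {g!r} outside (1, 2.2]: {e}")

    @classmethod
    def study_like(
        cls,
        n_genes: int = 10,
        n_stable: int = 2,
        stable_sd: float = 0.05,
        unstable_sd_range: tuple[float, float] = (0.4, 1.0),
        **kwargs,
    ) -> "SimulationConfig":
        """A candidate panel with a few genuinely stable genes.

        The unstable genes' noise SDs are spread evenly over
        ``unstable_sd_range`` so the true stability ordering is strict.
        """
        genes = [f"gene{i + 1:02d}" for i in range(n_genes)]
        lo, hi = unstable_sd_range
        n_unstable = n_genes - n_stable
        sds = {}
        for i, g in enumerate(genes):
            if i < n_stable:
                sds[g] = stable_sd
            else:
                j = i - n_stable
                sds[g] = lo + (hi - lo) * j / max(n_unstable - 1, 1)
        return cls(genes=genes, noise_sd=sds, **kwargs)


@dataclass
class SimulationTruth:
    noise_sd: dict[str, float]
    group_effect_magnitude: dict[str, float]   # sum of |delta| per gene
    loading_factors: pd.Series
    efficiencies: dict[str, float]
    stability_ordering: list[str]              # most stable first

    @staticmethod
    def _ordering(config: SimulationConfig) -> list[str]:
        key = {
            g: (
                config.noise_sd[g]
                + sum(abs(v) for v in config.group_effects.get(g, {}).values()),
                g,
            )
            for g in config.genes
        }
        return sorted(config.genes, key=lambda g: key[g])


def _metadata(design: list[SampleCell]) -> SampleMetadata:
    df = pd.DataFrame(
        [(c.sample_id, c.organ, c.stage, c.treatment) for c in design],
        columns=["sample_id", "organ", "stage", "treatment"],
    ).set_index("sample_id")
    return SampleMetadata(df)


def _group_label(cell: SampleCell, axis: str) -> str:
    return getattr(cell, axis)


def simulate_ct_dataset(
    config: SimulationConfig, seed: int
) -> tuple[CtMatrix, SampleMetadata, SimulationTruth]:
    """Draw one Ct dataset (with technical replicates) plus its truth."""
    ss = np.random.SeedSequence(seed)
    rng_load, rng_noise, rng_tech, _ = (np.random.default_rng(s) for s in ss.spawn(4))

    samples = [c.sample_id for c in config.design]
    loading = rng_load.normal(0.0, config.loading_sd, size=len(samples))
    n_g, n_s = len(config.genes), len(samples)

    x = np.zeros((n_g, n_s))
    for gi, g in enumerate(config.genes):
        delta = config.group_effects.get(g, {})
        shifts = np.array(
            [delta.get(_group_label(c, config.effect_grouping), 0.0) for c in config.design]
        )
        eps = rng_noise.normal(0.0, config.noise_sd[g], size=n_s)
        x[gi] = shifts + loading + eps

    cycles_per_log2 = np.array(
        [np.log(2.0) / np.log(config.efficiencies[g]) for g in config.genes]
    )
    a = np.array([config.baseline_ct[g] for g in config.genes])
    ct_true = a[:, None] - x * cycles_per_log2[:, None]

    reps = ct_true[:, :, None] + rng_tech.normal(
        0.0, config.tech_rep_sd, size=(n_g, n_s, config.n_tech_reps)
    )
    values = pd.DataFrame(reps.mean(axis=2), index=config.genes, columns=samples)
    ct = CtMatrix(
        values,
        efficiencies=pd.Series(config.efficiencies),
        replicates=reps,
    )
    truth = SimulationTruth(
        noise_sd=dict(config.noise_sd),
        group_effect_magnitude={
            g: sum(abs(v) for v in config.group_effects.get(g, {}).values())
            for g in config.genes
        },
        loading_factors=pd.Series(loading, index=samples),
        efficiencies=dict(config.efficiencies),
        stability_ordering=SimulationTruth._ordering(config),
    )
    return ct, _metadata(config.design), truth


def simulate_fragment_counts(
    config: SimulationConfig, seed: int
) -> tuple[ExpressionTable, SimulationTruth]:
    """Negative-binomial fragment counts on the same design and truth."""
    mu = config.fragment_mean or {g: 1000.0 for g in config.genes}
    disp = config.fragment_dispersion or {g: 0.0 for g in config.genes}
    for g in config.genes:
        if mu.get(g, 0.0) <= 0:
            raise ValueError(f"fragment mean must be positive for {g!r}")
        if disp.get(g, 0.0) < 0:
            raise ValueError(f"dispersion must be nonnegative for {g!r}")

    ss = np.random.SeedSequence(seed)
    rng_load, _, _, rng_counts = (np.random.default_rng(s) for s in ss.spawn(4))
    samples = [c.sample_id for c in config.design]
    loading = rng_load.normal(0.0, config.loading_sd, size=len(samples))

    rows = {}
    for g in config.genes:
        delta = config.group_effects.get(g, {})
        shifts = np.array(
            [delta.get(_group_label(c, config.effect_grouping), 0.0) for c in config.design]
        )
        mean = mu[g] * np.power(2.0, shifts + loading)
        d = disp[g]
        if d == 0:
            rows[g] = rng_counts.poisson(mean)
        else:
            size = 1.0 / d  # var = mu + d * mu^2
            p = size / (size + mean)
            rows[g] = rng_counts.negative_binomial(size, p)
    table = ExpressionTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype(float)
    )
    truth = SimulationTruth(
        noise_sd=dict(config.noise_sd),
        group_effect_magnitude={
            g: sum(abs(v) for v in config.group_effects.get(g, {}).values())
            for g in config.genes
        },
        loading_factors=pd.Series(loading, index=samples),
        efficiencies=dict(config.efficiencies),
        stability_ordering=SimulationTruth._ordering(config),
    )
    return table, truth


def simulate_dilution_series(
    efficiency: float,
    levels: int = 6,
    fold: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 20.0,
    gene: str = "gene",
    replicates: int = 1,
) -> DilutionSeries:
    """Standard-curve points from a serial dilution with known efficiency.

    Default is six five-fold dilutions. At efficiency E the noiseless Ct
    at relative amount d is intercept - log10(d)/log10(E), so the fitted
    slope is exactly -1/log10(E).
    """
    if not (1.0 < efficiency <= 2.2):
        raise ValueError(f"efficiency outside (1, 2.2]: {efficiency}")
    if levels < 3:
        raise ValueError("need at least 3 dilution levels")
    rng = np.random.default_rng(seed)
    log10_amount = np.repeat(
        np.array([-i * np.log10(fold) for i in range(levels)]), replicates
    )
    ct = intercept - log10_amount / np.log10(efficiency)
    ct = ct + rng.normal(0.0, noise_sd, size=ct.shape)
    return DilutionSeries(gene, log10_amount, ct)
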