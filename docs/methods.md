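# Methods

## Problem setting

Relative qPCR quantification reports a target gene's expression as a
ratio to one or more reference genes, so any instability in the
references propagates directly into the biology. For species without a
reference genome the candidate pool is assembled two ways: homologs of
classical housekeeping genes, and transcripts that look constitutively
expressed in an RNA-Seq survey of the same samples. This package
implements the full screening-and-evaluation pipeline on top of two
tabular inputs (a transcripts × samples abundance table and a genes ×
samples Ct matrix with per-gene amplification efficiencies) plus sample
metadata (organ, developmental stage, treatment).

## Data model and conventions

Tables are genes-as-rows, samples-as-columns; missing Ct is NaN and is
never imputed. Amplification efficiency E is carried on the
fold-per-cycle scale (E = 2.0 ⇔ 100%); inputs above 2.2 are interpreted
as percent and converted, since bench reports usually print percent.
Technical replicates are averaged to one Ct per gene × sample before
stability analysis — all four algorithms operate on one value per
sample — but the replicate-level values are retained for the validation
ANOVA, which needs within-group degrees of freedom.

Relative quantities use the geNorm convention Q = E^(Ctmin − Ct), so
each gene's most-expressed sample has Q = 1. The choice of the
reference point is immaterial: referencing to the mean Ct instead
rescales Q by a per-gene constant, which cancels in every log-ratio
statistic downstream (tested as a shift-invariance property).

## Stability estimators

**geNorm.** V_gk is the n−1 sample SD of log₂(Q_g/Q_k); M_g is the mean
over partners. Log base 2 throughout (Ct is a base-2-like scale).
Iterative exclusion removes the highest-M gene per round; a tie at the
maximum is broken by excluding the lexicographically last gene id, and
the tie-break is recorded in the output rather than left to iteration
order. The last two genes are reported as a pair sharing their mutual V
as M, matching how practitioners quote "best pair with M = x". The
V(n/n+1) series uses the ranked nested subsets; the default decision
threshold is 0.15 and the usability cutoff on full-set M is 1.5.
Missing values are dropped pairwise (per V_gk), not listwise.

**Model-based (NormFinder-style).** The published method is an ANOVA-like
variance decomposition; published reimplementations differ in the exact
bias constant, so the estimator here is fixed as this package's
contract: (1) x = log₂ Q; (2) per-sample centering z = x − mean over
genes (removes loading artifacts exactly — an exact, tested property,
not a statistical one); (3) per group, intragroup sample variance s²_gγ
bias-adjusted as σ̂²_gγ = max(s² − (mean of the other genes' s²)/(G−1),
10⁻⁸) — centering mixes 1/(G−1) of the other genes' noise into each
residual; the floor prevents negative variances; (4) intergroup
difference d_gγ = z̄_gγ − mean over groups, shrunk by
γ̂²/(γ̂² + σ̂²_gγ/n_γ) where γ̂² is the across-gene variance of d_·γ;
(5) ρ_g = mean over groups of |d̃_gγ| + √(σ̂²_gγ/n_γ). With one group
(used for single-condition subsets) all d vanish and ρ_g = σ̂_g. The
default grouping for all-sample analyses is treatment
(control/drought); organ and stage groupings are selectable. This
algorithm drops samples listwise (centering needs complete gene
vectors).

**BestKeeper.** Operates on raw Ct. Both dispersion variants are
computed — SD (n−1) and mean absolute deviation from the arithmetic
mean — because the original tool prints MAD while the "SD < 1 cycle"
stability rule is usually applied to whichever the report calls SD; the
ranking uses the configured variant (default SD). The index is the
per-sample geometric mean of candidate Cts; per-gene Pearson r against
the index gets a two-sided p from the exact t transform with n−2 df, no
multiple-testing correction. A zero-variance gene has undefined r,
reported as missing rather than 0. Note BestKeeper is deliberately NOT
loading-invariant: a sample-loading shift moves all Cts together and
inflates every SD (verified in tests), which is the known methodological
difference from the log-ratio methods.

**Comparative ΔCt.** Score = mean over partners of SD(Ct_g − Ct_k).
With all E = 2, log₂(Q_g/Q_k) = (Ctmin_g − Ctmin_k) − (Ct_g − Ct_k), a
constant minus the Ct difference, so the ΔCt score equals first-round
geNorm M exactly; this identity is asserted to 10⁻¹² on random inputs
as a cross-algorithm consistency oracle.

**Consensus.** Plain geometric mean of per-algorithm average ranks
(1 = most stable, ties share mean positions; a missing score ranks
last with a warning). The web tool this mirrors applies undocumented
internal weighting; that is intentionally not reproduced — the
geometric mean of ranks is the documented contract. Final ordering is
ascending with gene-id tie-break. Any ≥2 algorithms can be aggregated.

## Validation stage

Normalized expression of a target t against reference set R is
E_t^(Ct_t,cal − Ct_t,i) / geomean_{r∈R} E_r^(Ct_r,cal − Ct_r,i). With a
calibrator sample the calibrator's value is 1; without one, min-Ct
referencing leaves each set's series on an arbitrary per-set scale, so
before comparing sets each series is rescaled to geometric mean 1 —
only profile differences, never the arbitrary scale, can flag. The
per-group comparison is a one-way ANOVA across reference sets on log₂
normalized expression (log scale because qPCR ratios are log-normal-ish
and the algorithms all operate in log space), replicate-level when
technical replicates are attached. The significance level defaults to
α = 0.01. Normalizing against a set {A, B} equals the sample-wise
geometric mean of normalizing against A and against B alone (exact
identity, tested). Shared target noise across reference sets makes the
ANOVA conservative (measured null flag rate ≈ 0.3–0.7% at α = 0.01),
which is the right direction for a screening flag.

## Synthetic-data generator

The generator defines the study conditions. Log₂ expression is
x_gi = m_g + δ_{g,group(i)} + L_i + ε_gi with loading L_i ~ N(0, τ²)
(default τ = 0.2 log₂ units — a realistic pipetting/loading spread) and
biological noise ε ~ N(0, σ_g²). Ct follows as
Ct = a_g − x · ln2/lnE_g, with baseline intercepts a_g spread evenly
over 18–25 cycles (the range observed for real candidate panels) and
E_g = 2.0 unless configured. Three technical replicates add N(0, 0.1²)
cycles each. The default design is the 14-sample layout: leaf and fruit
at stages 3/4/7 and flower at the flowering stage, each under control
and drought. Fragment counts are negative binomial with mean
μ_g·2^(δ+L) and variance μ + d·μ² (d = 0 degenerates to Poisson).

The standard candidate panel (`SimulationConfig.study_like`) has 10
genes: two stable (σ = 0.05) and eight spread over σ ∈ [0.4, 1.0]. One
master seed spawns four fixed substreams (loading, biological noise,
technical replicates, counts), so changing e.g. τ leaves the noise draw
untouched — this is what makes the loading-invariance tests exact per
seed rather than only in expectation.

What the generator does **not** emulate: heteroscedastic Ct noise at
high cycle numbers, plate/batch effects, amplification inhibition,
correlated noise between genes, or count-level library-size estimation;
passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every real-world artifact.

## Numerical choices and degenerate inputs

Thresholds are strict inequalities everywhere the screening rules say
"greater/less than" (a transcript exactly at CV = 0.3 fails). SDs use
the n−1 denominator, which reproduces the bundled published CV cells
from their printed means/SDs to ≤10⁻³ relative error. Variance floor in
the model-based estimator: 10⁻⁸. Zero-mean transcripts fail the
prescreen with reason "zero mean" instead of raising. Fitted
efficiencies above 110% are flagged implausible (warning, not error);
non-negative standard-curve slopes invalidate the fit. Reports are
bit-stable: sorted JSON keys and repr-precision floats.

## Problem sizes used in the shipped experiments

The recovery and error-rate experiments in the tests and the acceptance
script use 100 simulation seeds at the default panel (10 genes × 14
samples, 3 technical replicates), 100 random instances for the exact
algebraic oracles, and n = 50 single-group samples for parameter
recovery — sizes at which the measured rates are stable from seed to
seed while the whole suite stays fast. Measured outcomes at these sizes:
top-2 consensus recovery 99–100/100 seeds, single-group noise-SD
ordering recovery ≈97/100, null validation flag rate well under 1%.

## Known limitations

* The model-based estimator is a fixed variant of a family of published
  NormFinder implementations; its absolute ρ values are not comparable
  across tools, only its ranking is.
* BestKeeper's regression diagnostics (slope/intercept per gene against
  the index) are not implemented; only the dispersion statistics and
  index correlation used for ranking are.
* The consensus does not reproduce any web service's hidden weighting.
* Printed stability values from published studies (M, ρ, BestKeeper SD,
  consensus ranges) cannot be recomputed without their raw per-sample
  Ct, which is not distributed; the bundled fixtures are summary tables
  only.
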