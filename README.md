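# refstab

Screening and evaluation of qRT-PCR **reference genes** (housekeeping
genes) for organisms without a reference genome, built around the
workflow used in plant transcriptomics: candidate genes are prescreened
from RNA-Seq abundance tables, their quantification-cycle (Ct) behaviour
is measured by qPCR, and their expression stability is ranked by four
independent algorithms whose ranks are merged into a consensus. A
ground-truth synthetic-data generator emulating a 14-sample design
(leaf/fruit/flower organs, developmental stages, control vs drought)
makes every stage testable without instrument data.

## Who this is for

Molecular biologists choosing normalization genes for qPCR experiments,
and bioinformaticians who want the stability algorithms as reusable,
tested library code rather than four separate Excel tools and a web
service.

## What it computes

* **Prescreen** — per transcript, mean abundance μ, sample SD s and
  CV = s/μ across samples; candidates satisfy the strict thresholds
  μ > 500 raw fragments and CV < 0.3.
* **Amplification efficiency** — from a serial-dilution standard curve,
  OLS of Ct on log₁₀(amount) gives slope b and
  E% = (10^(−1/b) − 1) × 100; E = 100% means perfect doubling (fold
  scale 2.0).
* **geNorm** — relative quantities Q = E^(Ct_min − Ct); for genes g, k,
  V_gk = SD(log₂ Q_g/Q_k); M_g = mean over k of V_gk. Iterative
  exclusion of the highest-M gene yields the ranking and the best pair;
  the pairwise variation V(n/n+1) = SD(log₂ NF_n/NF_{n+1}) of
  normalization factors (per-sample geometric means) decides how many
  reference genes are needed (threshold 0.15; M cutoff 1.5).
* **NormFinder-style model-based estimate** — after per-sample centering
  of log₂ quantities, a bias-adjusted intragroup variance σ̂²_gγ and a
  shrunken intergroup difference d̃_gγ are combined into the stability
  value ρ_g = mean_γ(|d̃_gγ| + √(σ̂²_gγ/n_γ)).
* **BestKeeper** — raw-Ct descriptives (geometric/arithmetic mean, SD,
  mean absolute deviation, CV%), the per-sample BestKeeper index
  (geometric mean of candidate Ct) and each gene's Pearson r against it;
  genes with SD < 1 cycle are flagged stable.
* **Comparative ΔCt** — a gene's score is the mean SD of its pairwise Ct
  differences against all other candidates (identical to first-round
  geNorm M when all E = 2).
* **Consensus** — per-algorithm average ranks are aggregated by
  geometric mean into a comprehensive value in [1, G]; agreement sets
  intersect each algorithm's top-k/bottom-k genes.
* **Validation** — a target gene is normalized against alternative
  reference sets via the efficiency-corrected ratio
  E_t^ΔCt_t / geomean_r E_r^ΔCt_r, and one-way ANOVA per sample group
  (α = 0.01) flags where the choice of normalizer changes the estimate.

## Worked example

```sh
refstab simulate --seed 11 --out demo
refstab evaluate --ct demo/ct.tsv --meta demo/meta.tsv --out demo_eval
```

prints `most stable pair by consensus: gene02, gene01` and writes
`demo_eval/stability.tsv`:

```
gene    genorm_score  genorm_rank  normfinder_score  ...  geomean_rank  final_rank
gene01  0.1147319463  1.5          0.03340787113     ...  1.861209718   2
gene02  0.1147319463  1.5          0.01709107289     ...  1.10668192    1
gene03  0.5455444511  5            0.1672246301      ...  4.053600464   4
```

The simulated panel has two genuinely stable genes (noise SD 0.05 log₂
units, `gene01`/`gene02`) among ten; all four algorithms put them first,
their geometric-mean consensus values (1.11 and 1.86) are the two
smallest, and geNorm reports them as the best pair with
V(2/3) = 0.135 < 0.15 — two reference genes suffice, so no third gene is
needed. `refstab prescreen --expr demo/expr.tsv --out screen.tsv`
applies the fragment-count screen (here `10 of 10 transcripts pass`,
since the simulated counts are high-abundance and low-dispersion), and
`refstab validate` compares normalization of a target gene under
alternative reference sets.

The package also ships the published per-gene summary tables of an
18-candidate Goji (*Lycium barbarum*) study
(`refstab.datasets.load_goji_rnaseq_summary()` /
`load_goji_qpcr_summary()`): RNA-Seq mean/SD/CV of raw fragments and
qPCR efficiency/R²/mean Ct/SD/CV, used throughout the tests as real
fixed points (e.g. applying the prescreen to the printed rows admits 12
of the 18 candidates, including the two novel stable genes LbCML38 and
LbRH52).

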