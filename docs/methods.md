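# Methods

This note documents the statistical model behind `mrmediate`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Two-sample MR model

A genetic instrument for an exposure X is a SNP j with association
estimate (βxⱼ, sexⱼ) in one GWAS cohort; the same SNP's association with
the outcome Y, (βyⱼ, seyⱼ), comes from a second, non-overlapping cohort.
Under the instrumental-variable assumptions (relevance, independence from
confounders, no effect on Y except through X), each SNP's Wald ratio
βyⱼ/βxⱼ estimates the causal effect of X on Y, and the IVW estimator
combines them as the zero-intercept weighted regression of βy on βx with
weights 1/se²yⱼ — algebraically identical to a fixed-effect meta-analysis
of Wald ratios under first-order weights (this equivalence is asserted to
1e-10 in the tests against an independently coded meta-analysis oracle).

**Random-effects flavor.** The IVW standard error is the fixed-effect
se₀ = (Σβ²x/se²y)^(-1/2) multiplied by max(1, √(Q/(J−1))) where Q is
Cochran's heterogeneity statistic. This multiplicative random-effects
model inflates uncertainty when the per-SNP estimates disagree but never
undercuts the fixed-effect SE — the floor prevents anti-conservative
inference when Q happens to fall below its expectation. Single-instrument
pairs fall back to the Wald ratio (tagged `wald_ratio`) rather than
failing the screen.

**p-values** for slopes, intercepts and proportions are two-sided normal.
This is the usual summary-level MR convention; an Egger small-sample t
alternative (t with J−2 df) would be slightly more conservative at small J
and could be added behind the same interface.

## Instrument selection

Filters run in the order p-threshold → LD clumping → F-statistic:

| parameter | default | meaning |
|---|---|---|
| `pval_threshold` | 1e-5 | strict upper bound on association p (suited to molecular traits whose GWAS rarely reach 5e-8) |
| `clump_r2` | 0.01 | maximum pairwise r² among retained SNPs within the window |
| `clump_window_kb` | 10,000 | window (kb) within which r² is compared on the same chromosome |
| `f_min` | 10 | per-SNP instrument strength F = (β/se)² below which SNPs are excluded |

Clumping is greedy by ascending p with ties broken by chromosome,
position, then rsID, making the output invariant to input row order; SNP
pairs beyond the window or on different chromosomes are never compared,
and pairs absent from the LD table are treated as independent (the number
of defaulted lookups is counted). The LD table is an explicit input — the
package deliberately does not ship or manage a reference panel, so the
caller (or the simulator) supplies pairwise r².

Note that with p computed from the same β/se as F, the per-SNP F filter is
redundant after `pval_threshold = 1e-5` (p < 1e-5 implies F > 19); it
becomes active when a file's P column disagrees with β/se or when looser
p-thresholds are used, and it is kept as an explicit, auditable stage.

## Harmonization

Effects are aligned to the exposure's effect allele: identical orientation
is kept, swapped effect/other alleles sign-flip the outcome β (and
complement its frequency), palindromic pairs (A/T, G/C) are removed
unconditionally — no allele-frequency-based strand inference is attempted,
trading a few SNPs for zero strand-misassignment risk — and any other
allele combination (for example, a strand-flipped record) is dropped as
incompatible. Instruments absent from the outcome panel are dropped with a
log entry; no LD-proxy search is performed. All removals are counted.

## MR-PRESSO

The global statistic is the leave-one-out residual sum of squares
RSS = Σⱼ (βyⱼ − β̂(−j)βxⱼ)²/se²yⱼ, compared against a parametric bootstrap
of the no-pleiotropy null (βy* ~ N(β̂(−j)βxⱼ, seyⱼ), βx* ~ N(βxⱼ, sexⱼ));
the per-SNP test compares each observed squared residual to its own
simulated distribution with Bonferroni adjustment across SNPs at 0.05; the
distortion test compares the relative change in the IVW estimate after
removing flagged outliers with the change from removing random SNP sets of
the same cardinality (simpler alternatives — a z-test on the two
estimates, or sign-free resampling — were considered and rejected as
either anti-conservative or unable to respect the outlier-set size).

Monte-Carlo p-values use the add-one rule, so they are never exactly zero
and are floored at 1/(n_sim+1). A practical consequence: with J SNPs the
smallest achievable Bonferroni-adjusted outlier p is J/(n_sim+1), so
n_sim must exceed J/0.05 − 1 for any outlier to be flaggable; the default
n_sim = 1000 comfortably covers screens with up to ~50 instruments. All
draws come from one seeded generator per invocation (no global state), and
results are reproducible bit-for-bit from (data, n_sim, seed).

## Mediation

The decomposition uses the product of coefficients: indirect = β₁β₂,
direct = β − β₁β₂, mediated proportion P = β₁β₂/β. Variances are
first-order delta method treating the three estimates as independent,
which matches the two-sample design (three non-overlapping cohorts); the
direct-effect SE likewise assumes independence of β and β₁β₂ and is
therefore approximate. The delta CI for P is symmetric while the sampling
distribution of a ratio is skewed, so its coverage is close to but not
exactly nominal (the test suite verifies 90–98% empirical coverage at 30
instruments and moderate effects). Triples where the indirect effect
opposes the sign of the total are flagged `inconsistent`: P is then not
interpretable as a fraction of the total effect.

## Pipeline conventions

- The outlier-corrected IVW (when MR-PRESSO flags) is the primary reported
  estimate; the uncorrected fit is retained in the JSON sidecar.
- A pair is "unidirectional" iff its forward fit is significant at α and
  its reverse fit is present and not significant; mediation triples
  require all three legs significant and unidirectional.
- Reverse-direction instrument selection uses the same thresholds as
  forward.
- Significance is nominal α = 0.05 with no multiple-testing correction;
  instead the output tables disclose the number of MR fits performed.
- Per-pair Monte-Carlo seeds are derived from the run seed and the trait
  identifiers (CRC32), so runs replay byte-identically (output floats are
  written with `%.17g`, which round-trips exactly).

## Synthetic-data generator

`simulate_triple` draws three summary-statistic panels on the causal
diagram X → M → Y with effects θ₁ (X on M), θ₂ (M on Y) and θ_d (X on Y
directly). Summary statistics are simulated directly at the summary level:
per-SNP MAF ~ Uniform(0.05, 0.5), standard errors follow the GWAS
approximation se = 1/√(2·MAF(1−MAF)·n), and observed effects are drawn
Normal(truth, se) independently per panel, emulating three non-overlapping
cohorts. p-values are two-sided normal, so null SNPs have exactly uniform
p.

Design choices that matter:

- **Each trait has its own J instruments.** Effects propagate downstream
  (an X-instrument affects M through θ₁ and Y through θ_d + θ₁θ₂) but
  never upstream. Mediator-specific instruments are what identify θ₂ —
  instruments inherited from the exposure estimate (θ_d + θ₁θ₂)/θ₁ on the
  M → Y leg, not θ₂ — and outcome-specific instruments are what give
  reverse MR something to fit (truthfully, a null).
- **Instrument magnitudes** are the positive half of Normal(0, γ_sd²)
  truncated to an expected-F window (default [100, 225], i.e. true z
  between 10 and 15). The truncation makes every planted instrument
  reliably discoverable at p < 1e-5 while keeping weights comparable; the
  positive orientation amounts to coding each effect allele as the
  trait-increasing allele, a lossless relabeling that also gives
  directional pleiotropy a well-defined sign for the Egger intercept.
- **Defaults** θ₁ = 0.25, θ₂ = 0.25, θ_d = 0.2375 give a total effect of
  0.3 with mediated proportion 0.208. The moderate leg effects keep the
  cross-trait contamination of instrument sets negligible: with θ₁ = 0.25
  an X-instrument's expected mediator-panel z is 2.5–3.75, below the
  selection threshold almost surely. Larger leg effects (e.g. θ₁ = 0.4)
  let X-instruments leak into the mediator's instrument set and bias the
  M → Y leg toward (θ_d + θ₁θ₂)/θ₁ — a genuine property of two-step MR,
  observable in the generator by construction, and the reason the
  parameter-recovery tests for the mediation algebra use the generator's
  truth-defined instrument sets.
- **Planted nuisance structure:** weak instruments (true effect √2·se,
  expected F ≈ 2), palindromic SNPs and null background SNPs carry no
  trait effect, so they fail the p-threshold and exercise the audit
  counters; allele-swapped (30%) and strand-flipped (5%) records in the
  downstream panels exercise the harmonization paths; optional outliers
  receive a horizontal-pleiotropy effect sized to a Wald ratio of 5× the
  true total; balanced or directional pleiotropy adds α ~ N(μ, σ²) direct
  SNP → Y effects on a chosen fraction of X-instruments.
- **LD blocks** group consecutive SNPs (members 10 kb apart, blocks
  20,000 kb apart) with a common within-block r²; the default block size
  of 1 yields fully independent SNPs.

What the generator does **not** emulate: realistic human LD structure,
sample overlap between cohorts, case-control ascertainment, MAF-dependent
effect-size architecture, and uncertainty in the LD table itself. Passing
tests therefore demonstrate the estimators' correctness and calibration
under the stated sampling model, not robustness to those real-data
complications.

## Problem sizes used in the test suite

Stochastic checks run at the study's desk-scale conditions: J = 30
instruments per trait, cohorts of n = 1e5, total effect 0.3. Replicate
counts are 200 for bias/coverage/uniformity checks, 1000 for the Egger
intercept type-I error, 50 for MR-PRESSO outlier detection (n_sim = 1000),
500 instances for the clumping brute-force comparison, and 200 end-to-end
pipeline replicates for mediated-proportion recovery (mean absolute error
< 0.05). Screening at α = 0.05 rejects a replicate's triple when a reverse
leg is spuriously significant (~5% per leg), so the end-to-end check
measures error over the replicates that assemble a triple — the designed
behavior of the screen.

## Known limitations

- Correlated instruments (generalized IVW), weighted-median/mode
  estimators, multivariable-MR direct effects and multiple mediators per
  triple are out of scope; the primary estimator is IVW only.
- Exposure effect scales are treated as unitless; no metadata tracks
  whether a panel is log-abundance, rank-normalized or log-odds beyond the
  binary/continuous trait-type tag.
- The mediated-proportion CI is delta-method and symmetric; for ratios
  near a null total effect it can be badly behaved (the proportion is
  undefined at β = 0 and the code raises rather than reporting a
  meaningless interval).
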