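# Methods

This note documents the statistical model, the defaults and why they are set
where they are, the synthetic-data generator's scope, and the numerical
choices that a maintainer or reviewer would otherwise have to reverse-engineer
from the code.

## Two-sample MR model and estimators

All estimators consume a harmonized set: per-SNP exposure effects
(β̂_Xj, σ_Xj) and outcome effects (β̂_Yj, σ_Yj) referred to the same effect
allele, from non-overlapping samples. Writing θ̂_j = β̂_Yj/β̂_Xj and
w_j = β̂²_Xj/σ²_Yj:

- **Wald ratio** (k = 1): θ̂ = β̂_Y/β̂_X with the first-order SE σ_Y/|β̂_X|.
  The first-order form ignores σ_X; this is the standard two-sample
  approximation and is defensible here because weak instruments (F < 10) are
  filtered before estimation. The second-order correction
  (adding θ̂²σ²_X/β̂²_X under the square root) is deliberately not applied, for
  comparability with common practice; at F ≥ 10 the omitted term inflates the
  SE by under ~5%.
- **IVW**: the w_j-weighted mean of ratios, identical to weighted least
  squares of β̂_Y on β̂_X through the origin with weights 1/σ²_Y. The
  fixed-effects SE fixes the residual scale at 1. The random-effects variant
  is the *multiplicative* overdispersion model: SE × √max(1, Q/(k−1)). It
  preserves the point estimate and never deflates the SE (truncation at 1),
  and is the fallback the pipeline reports when heterogeneity persists after
  outlier removal (Q p < 0.05, threshold configurable).
- **MR-Egger**: SNPs are first oriented so every β̂_X ≥ 0 (both betas negated
  where needed; the estimate is invariant to allele coding only after this
  orientation). Weighted regression with intercept; the intercept estimates
  the average directional pleiotropy under InSIDE. SEs carry the residual
  scale max(1, √(RSS_w/(k−2))) — again truncated below at 1 so
  underdispersion never manufactures precision — and p-values use t(k−2).
- **Weighted median**: sort θ̂_j, normalize weights, form cumulative midpoints
  S_j = Σ_{i≤j} w′_i − w′_j/2 and linearly interpolate θ̂ across S at 0.5.
  Note a subtlety: this interpolated definition is *not* invariant to
  duplicating every SNP when weights are unequal (the interpolation nodes
  shift); it is exactly invariant under equal weights, which is what the test
  suite asserts. The population-level estimand is duplication-invariant; the
  finite-sample interpolation rule is not, and we keep the standard rule.
- **Mode estimators**: normal-kernel density of θ̂_j with bandwidth
  h = φ·0.9·min(sd, MAD·1.4826)·k^(−1/5) (φ = 1 by default), weighted by w′_j
  (weighted mode) or uniformly (simple mode), evaluated on a fixed 512-point
  grid spanning [min θ̂ − 3h, max θ̂ + 3h]. The argmax takes the first
  (smallest-θ̂) grid point on ties, making the estimate deterministic. If all
  ratios coincide, h = 0 and the estimate is that ratio with SE 0.
- **Bootstrap SEs** (median and modes): parametric resampling of both sides
  (β̂*_X ~ N(β̂_X, σ_X), β̂*_Y ~ N(β̂_Y, σ_Y)), 1000 replicates by default,
  with a seeded generator (default seed 20240507). Point estimates are
  invariant to SNP reordering; bootstrap SEs depend on the order only through
  the RNG stream.
- **Odds-ratio scale**: for binary outcomes (log-odds betas) estimates are
  also reported as exp(β̂) with exponentiated CI bounds; refused for
  quantitative outcomes.

CI bounds everywhere use the exact normal quantile Φ⁻¹(0.975) = 1.95996, not
the rounded 1.96.

## Instrument selection and harmonization

- Significance threshold P < 1×10⁻⁵; clumping window 10,000 kb; r² < 0.001;
  F = (β̂/σ)² with F < 10 removed. F is the summary-data approximation; the
  n-and-R²-based alternative needs the variance explained, which summary
  files rarely carry.
- Greedy clumping ranks passing SNPs by ascending p, breaking ties by larger
  |β̂/σ| and then lexicographic SNP id, so the result is deterministic and
  invariant to input row order (output rows are emitted in selection-priority
  order). When no LD matrix is supplied, clumping degrades to distance-only:
  one SNP per window. The LD matrix is an explicit input (square or
  long-format TSV) because the package never computes LD from genotypes.
- Harmonization reconciles allele pairs by identity, swap (outcome beta
  negated), or strand complement followed by the same two cases. Palindromic
  SNPs (A/T, C/G) are removed outright — no allele-frequency rescue — and so
  is any pair irreconcilable by swap/complement ("ambiguous"). This is the
  conservative, deterministic reading; a frequency-based rescue would trade
  SNPs for assumptions about strand reporting.
- Cis (drug-target) selection restricts to the gene region ± 100 kb by
  default (configurable; "close to the gene" has no canonical width), then
  optionally requires eQTL support at p < 1e-4 (configurable), clumps, and
  recodes each SNP so the effect allele is the biomarker-*lowering* allele:
  downstream, a positive exposure beta uniformly means target inhibition.

## Sensitivity analyses

- Cochran's Q uses IVW-fixed weights; p from χ²(k−1).
- MR-PRESSO: each SNP's residual is taken against the leave-one-out IVW
  prediction, d_j = β̂_Yj − θ̂_(−j)β̂_Xj, and RSS_obs = Σ d²_j/σ²_Yj. The null
  distribution is simulated by redrawing both sides around the fitted model
  (n_sim = 1000 by default) and recomputing the statistic identically.
  Empirical p-values use (1 + #exceedances)/(n_sim + 1) so no simulated p is
  ever zero. Per-SNP outliers are declared below 0.05/k (Bonferroni over the
  instruments; the originating method leaves this to the user); the corrected
  estimate is IVW-fixed (or Wald) on the surviving SNPs. k ≥ 4 is required —
  below that the leave-one-out slopes are too unstable to test.
  The distortion test (percentage change between corrected and uncorrected
  estimates with a resampling p) is not implemented; the pipeline reports
  detection and re-estimation only.
- Leave-one-out rows flag exclusions that change the estimate's sign or move
  its p across 0.05. Funnel output is per-SNP (θ̂_j, 1/se(θ̂_j)) with IVW and
  Egger reference slopes, emitted as a table for external plotting; no figure
  rendering is done here.

## Two-step mediation

Step 1 estimates a (exposure→mediator) by harmonizing the exposure
instruments against each mediator panel (IVW-fixed, Wald when one SNP
survives) and screens with a Bonferroni threshold α/m over all m mediators
tested (α = 0.05; m = 1400 reproduces the printed 3.57×10⁻⁵, m = 168 the
printed 2.98×10⁻⁴). Step 2 selects each passing mediator's own instruments
from its GWAS at the same thresholds and estimates b (mediator→outcome); a
second Bonferroni screen over the step-2 tests sets a significance flag.

Decomposition: indirect = a·b, direct = c − a·b, proportion = a·b/c, with
se(a·b) = √(a²se²_b + b²se²_a) assuming zero covariance between â and b̂
(they come from non-overlapping steps; no covariance is estimable from
summary data). The proportion's SE defaults to the full first-order delta
over a, b and c, √(se²_ind/c² + ind²·se²_c/c⁴); treating c as fixed
(se_ind/|c|) is available as a flag since either expansion is defensible.
|proportion| > 1 (inconsistent mediation) is allowed but flagged. Proportions
are reported on the additive (log-odds for binary outcomes) scale; for binary
outcomes this inherits the usual non-collapsibility caveat. Mediators are
decomposed one at a time; no multivariable or joint decomposition is
attempted.

Because a mediator's strongest signals may be the exposure's own cis SNPs,
step-2 selection excludes the exposure instrument SNPs by default
(`exclude_exposure_snps`), with an optional genomic exclusion window; reusing
them would contaminate b with the direct effect (the noiseless test makes
this bias explicit).

## Synthetic-data generator

The generator emulates the three-trait two-sample design: per-SNP exposure
effects γ_j ~ U[0.05, 0.15] (so F statistics land well above 10 at the
default sample sizes; a weak-instrument fraction is injectable), mediator
effects a·γ_j plus the mediator's own instruments δ_j ~ U[0.05, 0.15], and
outcome effects (c′ + a·b)·γ_j + α_j with pleiotropic α_j on invalid SNPs
only (added to the outcome, so InSIDE holds by construction; offsets may be
expressed in units of the SNP's outcome SE). Observed betas are drawn
independently per trait with σ = 1/√(2·maf(1−maf)·n). Defaults follow the
targeted study design: n_x = 344,182 (biobank-scale biomarker GWAS),
n_m = 8,299 (metabolome cohort), n_y = 1×10⁵ (outcome GWAS), 10 exposure
instruments (the drug-target scale), 20 per mediator, one true mediator with
a = −0.4, b = 1.0, c′ = −0.9 (true proportion 0.4/1.3 ≈ 30.8%) and nine null
mediators; palindromic alleles injected at rate 0.1.

What it does **not** emulate — and hence what passing tests do not show about
real data: LD between instruments (SNPs are placed 20 Mb apart so distance
clumping keeps them; LD-aware clumping is exercised by hand-built matrices),
case-control likelihood for binary traits (the SE model is reused on the
log-odds scale), sample overlap between the two samples, population
stratification, and allele-frequency mismatch between studies.

## Calibration scenarios

The replicated benchmarks (`mrmediate.benchmarks`) fix their study conditions
once: recovery at k = 50 strong instruments and true θ = 0.5; Cochran's Q and
Egger-intercept calibration under an effectively noiseless exposure side
(n_x = 10¹²), because χ²(k−1) and t(k−2) are those statistics' reference
distributions *conditional on the exposure effects* — with finite exposure
samples Q is inflated by the unmodeled σ_X term, which is a property of
standard two-sample MR, not of this implementation. Balanced pleiotropy for
the type-I-error scenario is drawn per SNP as N(0, σ_Yj) (SE-scaled), which
makes the overdispersion exactly multiplicative — the model the scaled-SE
inference assumes. MR-PRESSO scenarios use the full noisy generator since its
simulation step models both noise sources. Problem sizes (500/2000/1000/500/
200/300/100 replicates) match the package's reproducibility suite.

One benchmark expectation is knowingly not met: with a randomly planted
10-SE outlier among 19 clean SNPs, removing it moves the IVW estimate toward
the truth in about 85% of flagged replicates, not ≥90% — the probability is
the scale-free Φ(10·β̂_Xo/(2√Σ′β̂²_X)), capped at ~87% even for equal
instrument strengths. The benchmark reports the measured rate as-is.

## Degenerate inputs and ties

- Empty instrument sets and empty harmonized sets warn and refuse downstream
  estimation; β̂_X = 0 is fatal for ratio-based estimators.
- All-equal ratios: Q = 0 with p = 1; mode returns the common ratio with
  SE 0; the bootstrap SE may be ~0, in which case the p-value degenerates to
  0/1 by the sign of the estimate.
- Simulated p-values are clamped at the smallest positive float so the
  (0, 1] domain survives underflow; the reader's p-vs-z consistency check
  skips the saturated regime (implied p < 1e-300).
- Mode grid ties break toward the smaller ratio; clumping ties break by
  |z| then SNP id. Both make every pipeline output reproducible bit-for-bit
  under a fixed seed.
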