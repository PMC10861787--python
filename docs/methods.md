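# Methods

## Model and assumptions

Two-sample MR treats genetic variants as instruments for an exposure. The
three instrumental-variable conditions are: *relevance* (the SNP is robustly
associated with the exposure — enforced here as p < 5×10⁻⁸), *independence*
(the SNP is not associated with exposure–outcome confounders — represented
by an explicit, user-supplied SNP blocklist; the package never queries
external annotation services), and *exclusion restriction* (the SNP affects
the outcome only through the exposure — probed, not guaranteed, by the
pleiotropy diagnostics).

Estimation works entirely with per-SNP summary coefficients. Outcome betas
are log-odds for binary traits, so causal estimates exponentiate to odds
ratios; a 95% CI is reported on the OR scale throughout.

## Instrument selection and harmonization

Clumping is greedy in ascending p-value order (ties broken lexicographically
by rsID, so results are independent of input row order): a SNP is kept
unless it has r² ≥ 0.001 with an already-kept SNP on the same chromosome
within 10 000 kb. LD is supplied as a plain three-column table; when absent,
instruments are assumed independent and a warning is emitted. Positions are
1-based and the window is |Δpos| ≤ window·1000 bp.

Harmonization matches on rsID (the granularity at which GWAS hits are
published), aligns the outcome's effect allele to the exposure's — negating
the outcome beta for swapped alleles, resolving strand flips by
complementing — and drops palindromic A/T–C/G pairs unconditionally by
default, since their strand cannot be read off the alleles. An opt-in mode
infers palindrome strand from allele frequencies when both are outside
[0.42, 0.58]; frequencies on the same side of 0.5 imply alignment. Exposure
instruments missing from the outcome GWAS are skipped and counted (no proxy
lookup). The kept set plus the drop log always partition the shared SNPs.

## Estimators: numerical choices

- **Wald ratio SE** uses the first-order delta method σ_Y/|β̂_X|, the
  convention that makes IVW algebraically identical to the no-intercept
  weighted regression of outcome on exposure betas (the package's tests
  verify this equivalence against the normal equations). A second-order
  variant adding the exposure-uncertainty term is available behind a flag.
- **IVW** defaults to multiplicative random effects, SE × √max(1, Q/df):
  with real instruments heterogeneity is the rule, and the inflation is
  clipped at 1 so the random-effects CI is never narrower than the
  fixed-effect one. Both flavors are reported by the tidy `mr_all` table.
  IVW p-values use the standard normal.
- **MR-Egger** orients every SNP to a non-negative exposure effect before
  fitting (the intercept is only meaningful in that orientation), weights by
  1/σ²_Y, and takes slope/intercept p-values from a t distribution on J−2
  df. The weighted residual sum of squares is Rücker's Q.
- **Weighted median** sorts the Wald ratios, forms cumulative weight
  midpoints pⱼ = Σ_{k≤j} w′_k − w′_j/2, and linearly interpolates the ratio
  at p = 0.5 (clamped at the extremes). The SE is a parametric bootstrap —
  betas resampled from their reported normal sampling distributions —
  with 5000 replicates by default (SE stable to about two decimals) and an
  explicit seed; fewer than 100 replicates is rejected as a configuration
  error.
- **Significance** for all MR conclusions is the conventional p < 0.05, with
  no multiplicity correction by default.

## MR-PRESSO

The observed statistic is the leave-one-out residual sum of squares:
RSS = Σⱼ wⱼ (β̂_Yj − β̂₍₋ⱼ₎ β̂_Xj)² with wⱼ = 1/σ²_Yj and β̂₍₋ⱼ₎ the IVW
slope excluding SNP j. The null distribution is parametric: each simulated
dataset draws β*_Xj ~ N(β̂_Xj, σ_Xj) and β*_Yj ~ N(β̂₍₋ⱼ₎ β̂_Xj, σ_Yj) and
recomputes the entire statistic, including the leave-one-out slopes.
Empirical p-values use add-one smoothing, (1 + #{sim ≥ obs})/(n_sim + 1), so
the smallest reportable p is 1/(n_sim+1); the default n_sim = 10 000 gives
10⁻⁴ resolution, and fewer than 1000 simulations is rejected. Per-SNP
outlier p-values are each SNP's observed RSS component against its own
simulated distribution, Bonferroni-adjusted by J and flagged at 0.05. The
distortion test compares the raw-minus-corrected slope shift against the
removal of random subsets of the same size (two-sided empirical p). At least
4 instruments are required; with fewer, callers report "not applicable" and
pass the data through, so small-instrument analyses still run.

A caution surfaced by simulation: a sufficiently extreme outlier contaminates
the leave-one-out fits of *other* SNPs, which can push clean SNPs past the
outlier threshold as well. When removal would leave fewer than two
instruments the procedure raises an error rather than returning a corrected
estimate from nothing.

## Multivariable MR and mediation

The joint model regresses outcome betas on the K exposures' beta matrix
(no intercept, weights 1/σ²_Y); coefficient k is exposure k's direct effect.
SEs use the weighted-least-squares covariance scaled by √max(1, Q/(J−K)),
mirroring the univariable convention, with two-sided normal p-values. An
all-zero exposure column (a degenerate but well-posed case) is assigned a
zero effect with infinite SE and the fit proceeds on the remaining columns;
linearly dependent nonzero columns raise a collinearity error. Instrument
pooling takes the union of each trait's clumped instruments, re-clumps
jointly (each SNP carrying its smaller p), and aligns mediator and outcome
effects to the exposure's effect alleles.

Mediation runs three univariable legs (β_A: exposure→mediator, β_B:
mediator→outcome, β_C: exposure→outcome). With full data the difference
method applies: indirect = β_C − β_C′ from the joint model. "Significant
attenuation" is operationalized as β_C′ significant (p < 0.05) *and*
|β_C′| < |β_C| *and* an implied proportion > 0 — the strictest reading
consistent with requiring an attenuated, still-present direct effect.
Without full data, the Sobel product method applies: indirect = β_A β_B with
SE √(β_A² S_B² + β_B² S_A²) and a two-sided standard-normal p (no
Aroian/Goodman variants). In both routes the verdict additionally requires
all three legs significant. Proportions are indirect/β_C, printed as
percentages to two decimals; sign-inconsistent values outside [0, 1] are
flagged, never clipped. When both path coefficients are exactly zero the
Sobel statistic is undefined and p = 1 is reported.

## Synthetic data: what it emulates, and what it does not

The generator is summary-level: estimated betas are drawn around their true
values with SE = 1/√(n·2f(1−f)), allele frequencies Uniform(0.05, 0.95).
True instrument effects |γ| are Uniform(0.03, 0.10) with random sign,
scaled by an instrument-strength multiplier; at the default study sizes
(exposure 200k, mediator 150k, outcome 300k persons) this makes essentially
all instruments genome-wide significant, isolating estimator behavior from
selection effects. The causal structure is θ_total = θ_direct + a·b by
construction, with per-SNP pleiotropy α added to the outcome:
balanced α ~ N(0, sd); directional α aligned with the exposure-increasing
orientation (otherwise sign-orientation would cancel it and MR-Egger could
never see it). Mediator-specific instruments are extra SNPs with γ = 0 and
their own mediator effects δ from the same distribution — without them the
mediator would have no instruments of its own and the β_B leg and the joint
model would be unidentified. Sample overlap is approximated by correlating
the exposure and outcome sampling errors with correlation equal to the
overlap fraction — a shortcut for shared participants that reproduces the
qualitative phenomenon (winner's-curse bias toward the confounded
association, inflated type-I error under the null) without individual-level
data. Planted outliers receive pleiotropy that inflates their outcome effect
to a configurable multiple (default 10×) of the model-implied value.

Not emulated: LD between instruments (clumping is exercised with synthetic
r² tables instead), liability-scale conversion for binary traits, population
stratification, and real minor-allele-frequency spectra. Passing tests on
this generator therefore demonstrate estimator algebra and statistical
calibration under the stated model, not robustness to everything real GWAS
data can do.

## Simulation scenarios used by the test suite

Problem sizes were chosen so each check measures what it claims at desk
scale: CI coverage with J = 50 strong instruments, θ = 0.5, 500 replicates;
Egger calibration/power with exposure n = 10⁶ (the intercept test's nominal
level relies on negligible exposure measurement error — at smaller n the
known attenuation artifact inflates its type-I error, which is visible in
the generator if provoked) and directional pleiotropy mean 0.01, sd 0.005;
outlier recovery with a 10× outlier among 20 clean SNPs at θ = 0.1, chosen
so the outlier's deflection dwarfs noise while its contamination of the
clean SNPs stays within noise; mediation recovery with a = 0.3, b = 0.7,
θ_direct = 0.2 over 200 replicates. The overlap experiment uses an
instrument-strength multiplier of 0.35 so the significance filter actually
binds, which is what lets overlap bias manifest.

## Known limitations

- One mediator at a time; no multi-mediator joint decomposition and no CI
  for the mediated proportion.
- No mode-based, robust-regression (RAPS), or Bayesian estimators.
- The confounder screen is only as good as the supplied blocklist.
- No proxy-SNP lookup for instruments missing in the outcome GWAS; they are
  dropped and counted.
- Summary-level overlap emulation cannot capture cohort-specific artifacts.
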