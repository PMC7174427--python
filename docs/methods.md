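# Methods

This note documents the statistical procedures implemented in `causalmr`,
the assumptions behind them, the defaults and why, and what the synthetic
generator does and does not emulate.

## Setting and assumptions

Two-sample MR with summary statistics: instrument–exposure effects
(continuous exposure, SD units after inverse-rank normalization) come from
one GWAS, instrument–outcome effects (binary outcome, log-odds) from a
non-overlapping case–control meta-analysis. A variant is a valid instrument
if it is (i) associated with the exposure, (ii) independent of confounders,
and (iii) affects the outcome only through the exposure. The estimator and
diagnostic battery exists because (iii) — no horizontal pleiotropy — is
untestable directly and must be probed from several directions at once.

## Instrument construction

- **Clumping** (`ld_clump`): greedy by ascending p-value; a lead removes all
  variants with r² ≥ 0.005 within ±5 Mb on its chromosome. Sub-threshold
  (P ≥ 1×10⁻⁸) variants never lead and never suppress. Ties in p are broken
  by (chrom, pos, id) for determinism; the source GWAS is silent on
  tie-breaks and they only matter for identical floating-point p-values.
- **Loci** (`define_loci`, `merge_cross_trait_loci`): ±1 Mb around each
  lead; overlapping same-trait loci collapse to the most significant lead,
  and cross-trait leads within 1 Mb merge, keeping the union of trait
  labels. Both functions default to transitive closure (chains longer than
  2 Mb can merge), which is order-invariant; a single-pass mode is
  selectable for the literal one-sweep re-search behaviour. The closure
  default is a deliberate deviation chosen for order-invariance.
- **Strength**: per-variant r² is available as 2·EAF·(1−EAF)·β² (valid for
  SD-scale continuous traits) or t²/(t²+n−2) (any trait, observed scale);
  F = R²(n−2)/(1−R²) with F ≤ 10 flagged weak. I²<sub>GX</sub> is the
  Cochran statistic of the instrument–exposure effects themselves,
  max(0, (Q<sub>GX</sub>−(k−1))/Q<sub>GX</sub>); below 0.95 the Egger slope
  carries a measurement-error (NOME-violation) warning but is still
  reported — with few or homogeneous instruments the index collapses to 0
  even when instruments are individually strong, so suppressing Egger on it
  would discard information.
- **Steiger filter**: per variant, r² against exposure and outcome via the
  t-statistic form; |r| values compared by a Fisher-z two-sample test
  (z-difference over √(1/(n_X−3)+1/(n_Y−3)); the two-sample design
  guarantees independent samples). A variant is removed only when the
  outcome r² is larger *and* the test is significant at α = 0.05 — an
  insignificant difference keeps the variant. The binary outcome's r² is an
  observed-scale approximation; since only the comparison matters, scale
  constants cancel to first order.
- **Pleiotropy exclusion**: consumes an external (variant, trait) table —
  e.g. derived from a GWAS-catalog query — and removes listed instruments,
  optionally extending removal to instruments in LD > 0.8 with a listed
  variant. The table is an input, never computed here.

## Harmonization

All effects are oriented to the first exposure table's effect allele per
variant: an allele swap negates β and complements EAF; a strand flip
complements alleles first. Missing variants are dropped, never proxied.
Palindromic (A/T, C/G) variants cannot be strand-resolved from alleles;
default policy drops them when EAF ∈ [0.42, 0.58] in any table (the common
two-sample convention), with `infer_by_eaf` and `keep` selectable. Indels
are accepted but never treated as palindromic. A p-vs-z consistency check
warns (never errors) at more than half an order of magnitude disagreement,
since published tables round aggressively.

## Estimators

Wald ratios use first-order SEs σ<sub>Yj</sub>/|β<sub>Xj</sub>| — the
dominant convention — with the understanding that they ignore exposure-side
noise (the NOME caveat above). Design choices:

- **IVW**: fixed-effects SE (Σw)<sup>−1/2</sup>; the random-effects model is
  multiplicative with the dispersion factor floored at 1, so underdispersion
  is never rewarded and the point estimate is identical under both models.
  One instrument degenerates to the Wald ratio. p-values are normal.
- **Egger**: weighted least squares with free intercept on instruments
  oriented β<sub>X</sub> > 0; SEs use the unscaled covariance times
  max(1, √(Q′/(k−2))) and p-values use t with k−2 df, matching the
  reference implementations of the method. Requires k ≥ 3.
- **Weighted median**: interpolation of the standardized cumulative weights
  p<sub>j</sub> = (S<sub>j</sub>−w<sub>j</sub>/2)/S<sub>k</sub> at 0.5;
  SE from a parametric bootstrap θ* ~ N(θ̂<sub>j</sub>, σ<sub>j</sub>),
  default 1,000 draws, seeded. The estimator is consistent when valid
  instruments carry ≥50% of weight; its finite-sample bias is of the order
  of the Wald-ratio noise, which is why robustness claims are only
  meaningful in the strong-instrument regime.
- **Weighted mode**: argmax of a normal-kernel weighted density of the
  ratios, bandwidth φ·0.9·min(sd, IQR/1.349)·k<sup>−1/5</sup> (weighted
  modified Silverman, φ = 1 by default); the argmax is located on a
  10,000-point grid and refined to 1e-8. Zero bandwidth (identical ratios)
  returns that ratio. Bootstrap SE as for the median.
- **MR-PRESSO**: observed statistic is the weighted sum of squared
  leave-one-out residuals (β<sub>Yj</sub> − θ̂<sub>−j</sub>β<sub>Xj</sub>);
  the null distribution is built from parametric draws of both effect
  columns (default 1,000). Empirical p-values are floored at 1/(n_sim+1);
  the per-variant outlier p is Bonferroni-multiplied by k, which implies a
  detection floor of k/(n_sim+1) — at the default significance 0.05, k=30
  requires n_sim ≥ ~600. The corrected estimate is the IVW fit without
  outliers; the distortion test compares the raw-vs-corrected shift against
  removal of equal-sized random subsets and is reported but not used as a
  gate. Requires k ≥ 4.
- **Model decision**: random-effects IVW replaces fixed when I² > 25% *and*
  Cochran p < 0.05 (both printed criteria combined conjunctively — the
  conservative reading). Q, Q′ and Q−Q′ use χ² references with k−1, k−2 and
  1 df respectively.

## Multivariable MR

Weighted regression of β<sub>Y</sub> on the k×E matrix of exposure effects,
no intercept, weights σ<sub>Y</sub><sup>−2</sup>; SEs carry the same
floored dispersion scaling. Conditional instrument strength Q<sub>xj</sub>
is the weighted residual sum of squares of exposure j's effects after
regressing out the other exposure's (weights σ<sub>Xj</sub><sup>−2</sup>, no
intercept), compared to the χ²(0.95, k−2) critical value; this residual-
dispersion construction is the module's key reconstruction — only the df
and the decision rule are fixed by convention, so the formula is validated
against this package's own simulations (proportional effect columns give
Q<sub>x</sub>=0; independent strong columns exceed the critical value), not
against external output. Q<sub>a</sub> is the fit's weighted residual sum
against χ²(0.95, k−3). E = 2 is the designed case; E > 2 is available
behind a flag. Secondary-exposure effects estimated in the same cohort as
the primary can reintroduce covariance between the two effect columns; no
covariance correction is attempted and the caveat travels with the result.

The attenuation report compares total (univariable) and direct
(multivariable) effects: proportional attenuation 1 − θ_direct/θ_total on
the log-odds scale, a CI-overlap indicator, and a label — `independent`
when the direct CI excludes the null, `vertical-pleiotropy-consistent` when
the direct effect is attenuated toward the null with the same sign.

## Synthetic data generator

`simulate_two_sample` draws, per instrument: MAF ~ U(0.01, 0.5); true effect
b<sub>j</sub> ~ N(0, beta_dist²) in SD units;
σ<sub>Xj</sub> = (2·MAF(1−MAF)·n_exp)<sup>−1/2</sup>; observed effects
normal around truth. The outcome SE uses the case-fraction-scaled binary
approximation (2·MAF(1−MAF)·n_out·cf(1−cf))<sup>−1/2</sup>. Defaults mirror
the motivating study: n_exp = 408,815; n_out = 184,305 with case fraction
0.33; θ = 0.365 log-odds per SD (OR 1.44); beta_dist = 0.025 SD, a typical
scale for behavioural-trait GWAS hits at biobank size, putting
genome-wide-significant instruments' F-statistics in the tens-to-hundreds.
p-values are computed from the normal z-score, so generated tables satisfy
the p–z invariant by construction. One root seed is split into independent
sub-streams per component.

Pleiotropy scenarios: `balanced` (α ~ N(0, σ<sub>α</sub>²)), `directional`
(α ~ N(μ<sub>α</sub>, σ<sub>α</sub>²) applied **relative to the
exposure-increasing allele** — estimators re-orient instruments to
β<sub>X</sub> > 0, and a shift defined in raw allele coding would average
out under that orientation), `inside_violation` (α correlated with b at a
set ρ), and `outliers` (m variants spiked by a fixed amount). An optional
second exposure with instrument loading γ (b2 = γ·b + noise) and its own
outcome effect creates mediation/confounding structure for multivariable
scenarios; the implied total univariable effect is θ + θ₂·γ and is recorded
in the truth block along with every per-variant effect.

What the generator does **not** emulate: LD between instruments (the
separate `simulate_ld_region` provides an exponential-decay r² region for
clumping tests only), population structure and relatedness, allele-frequency
differences between the two samples, winner's-curse-free replication
(instruments selected at P < 1×10⁻⁸ in the same simulated GWAS carry the
same selection bias a real one-sample discovery does — visible as a small
attenuation of ratio estimates and, in multivariable fits with correlated
effect columns, a transfer of effect between columns), imputation quality,
or the meta-analytic SE heterogeneity of a real consortium outcome GWAS
(whose printed confidence intervals are accordingly wider than the
approximation's). Passing tests therefore demonstrate correctness of the
estimators and decision logic under the stated generative model, not
robustness to those unmodelled features.

`inverse_rank_normalize` is the Blom-offset rank transform
Φ⁻¹((r−3/8)/(n+1/4)) with average ranks on ties — the transform that puts a
right-skewed phenotype (hours of television) on the SD scale on which all
exposure effects are interpreted.

## Pipeline

`run_mr_suite` executes, per exposure and per threshold on the ladder
{1×10⁻⁸ (primary), 5×10⁻⁸, 1×10⁻⁷, 1×10⁻⁶, 1×10⁻⁵}: selection (clumping if
an LD matrix is supplied) → harmonization → strength QC → Steiger → IVW
with the model decision → Egger + Rucker selection → weighted median/mode →
MR-PRESSO → exclusion reruns (education-only and all-traits) → per
secondary exposure, a univariable exposure-on-secondary MR followed by the
multivariable fit and attenuation report. Stage failures are recorded
per cell and never abort the battery; every estimate carries its instrument
count and seed, and per-cell seeds derive deterministically from the
manifest seed. Default stage order is Steiger before the estimators (both
orders are defensible; the filter is cheap and the order is visible in the
report's drop accounting).

## Problem sizes in the checks

The test suite's simulation-based checks use 30–60 replicates at k = 30–150
with bootstrap draws reduced to the minimum needed for the quantity under
test (point-estimate checks use nboot = 2); type-I calibration uses 1,000
replicates for the Egger intercept and 200 for the MR-PRESSO global test
(n_sim = 300). The acceptance script simulates one study per trait and per
multivariable adjustment at full sample size with n_sim = nboot = 1,000,
candidate instrument counts (380/90/10) chosen so the expected
genome-wide-significant count matches the published 152/37/4, and a
true-effect spread of 0.02 SD so selected instruments' F-statistics sit in
the published range (minimum ≈ 30). Reported quantities are single-study
realizations, as the original estimates are.

## Known limitations

- First-order Wald weights understate exposure-side noise; the I²GX warning
  is the guard, not a correction (no SIMEX).
- The weighted-mode bandwidth constant follows the modified-Silverman rule;
  mode estimates are bandwidth-sensitive for small k.
- MR-PRESSO's distortion null resamples subsets of all instruments rather
  than conditioning on outlier status.
- Correlated instruments are out of scope: clumping at r² < 0.005 is assumed
  to have made instruments effectively independent.
- Binary secondary exposures in multivariable fits are treated as given
  numeric effect columns (log-odds), without scale translation.
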