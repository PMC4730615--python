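# Methods

## Model and estimators

Subjects are independent draws (Y_i, g_i) with genotype g the
minor-allele count at a biallelic SNP.  All inference is built on the
win probabilities f_ab = Pr(Y_a < Y_b) between genotype groups.  The
plug-in estimator f̂_ab averages the strict indicator I(y_i < y_j) over
all cross-pairs; its variance plug-in is the usual two-sample
Hájek-projection form — two sums of squared centered comparison
fractions plus the constant 1/(4 n_a n_b) — and the covariance between
two win probabilities sharing a group averages, over the shared group,
the product of the two centered opposite-group comparison fractions.
All are computed in O((n_a + n_b) log n) via sorting, and all depend on
the data only through ranks, so every downstream statistic is exactly
invariant under strictly increasing trait transforms.

Strict inequality is the default tie rule (continuous traits); a
`ties="midrank"` option scores ties 1/2 for traits with point masses
(e.g. imputed detection limits).  One index inconsistency in the
σ̂₁₂² projection sum (an i where only j is in scope) is resolved the
only way that parallels the σ̂₀₁² term.

Phase-2 statistics: Z_R standardizes the pooled contrast
(n₀ f̂_02 + n₁ f̂_12)/(n₀+n₁); Z_D mirrors it from the other end;
Z_A combines f̂_01 and f̂_12 with inverse-standard-error weights
w₁* = √((n₀+n₁)/((n+n₁) σ̂₀₁²)), w₂* = √((n₁+n₂)/((n+n₁) σ̂₁₂²)),
normalized to sum to one.  Each is asymptotically N(0,1) under the
null (verified by a 10,000-replicate KS check in the test suite).
MAX3 = max(|Z_R|, |Z_A|, |Z_D|).

## Model selection and size adjustment

Z₁ = (f̂_01 − f̂_12)/√(σ̂₀₁² − 2σ̂₀₁,₁₂² + σ̂₁₂²) contrasts the two
adjacent-group win probabilities: a dominant effect pushes f_01 up, a
recessive one pushes f_12 up, an additive one moves both equally.  The
rule is DOM if Z₁ > ξ, REC if Z₁ < −ξ, else ADD, with ξ a standard
normal quantile (default Φ⁻¹(0.90); boundary values go additive).

Because phase 2 reuses the data that selected the model, testing at the
nominal α would inflate the size.  Under the null (Z₁, Z_x) is
asymptotically bivariate normal with correlation ρ_x, and α* solves

    α = Σ_x ∫_{Ω_x} [Φ((−c − ρ_x u)/s_x) + Φ((−c + ρ_x u)/s_x)] dΦ(u),

c = z(1 − α*/2), s_x = √(1 − ρ_x²), Ω_R = {u < −ξ}, Ω_A = {|u| ≤ ξ},
Ω_D = {u > ξ}.  The right side is strictly increasing in α*, so the
root is unique; it equals α exactly when all ρ_x = 0 and in the
|ρ_x| → 1 limit, and sits below α for the correlations real data
produce.

**Correlation convention.**  Two defensible ρ's exist and the package
implements both.  The `"pooled"` delta method propagates the plug-in
covariance of (f̂_01, f̂_12, f̂_02) through the literal numerator
weights of Z_x and consistently estimates corr(Z₁, Z_x) — it matches
the Monte-Carlo correlation of the two statistics to within sampling
error.  The default `"adjacent"` convention instead represents each
phase-2 statistic by its adjacent two-group contrast (REC by f̂_12,
DOM by f̂_01, ADD by the weighted pair), the representation under
which the size adjustment was derived; it yields larger |ρ| and hence
a smaller, more conservative α* (≈ 0.031 vs ≈ 0.036 at MAF 0.25,
α = 0.05).  Both keep the empirical size at or below nominal; the
default reproduces the procedure's reference behavior.  ADD's weights are treated as
constants at their observed values — their sampling variability is
second order.

**Numerics.**  The u-integral uses Gauss–Legendre quadrature, 200
nodes per region, truncated at |u| = 8 (neglected normal mass
< 1e-15); nodes are cached per ξ.  |ρ| within 1e-9 of 1 switches to
the closed-form degenerate limit.  The root is bracketed on
(1e-13, 1 − 1e-13) and solved with Brent's method at xtol 1e-12.
Denominators below 1e-12 anywhere raise a degenerate-statistic error
rather than dividing through; no statistic ever returns NaN silently.

**Small-group fallback.**  The variance plug-ins need every genotype
group of size ≥ 2; at MAF 0.05 and n = 1500 the minor-homozygote group
fails this in roughly 11% of Hardy–Weinberg draws.  The full selection
apparatus (and even Z_A, whose variance involves σ̂₁₂²) is then
undefined, so the procedure pools the deficient homozygote group with
the heterozygotes and applies the two-group win-probability test at
the *unadjusted* α, flagging the result `fallback=True` and logging a
warning.  Experiment drivers count fallback replicates separately
rather than redrawing, which would bias the genotype distribution.

MAX3's asymptotic p-value needs the box probability of a trivariate
normal with delta-method correlations; it is computed by a
deterministic tensor Gauss–Legendre quadrature (48² nodes over the
first two coordinates, the third integrated in closed form
conditionally), so repeated runs are bitwise identical — a property a
quasi-Monte-Carlo CDF call would not give.  A seeded genotype-label
permutation method is the cross-check, and the two agree within
Monte-Carlo error in the test suite.

## Synthetic data

The generator emulates the validation conditions for the procedure:
Hardy–Weinberg genotypes at a given MAF (minor-allele counts
Binomial(2, p)), and the linear trait model
Y = β₀ + score(g)·β₁ + ε with scores REC (0,0,2), ADD (0,1,2),
DOM (0,2,2) — chosen so the two-homozygote contrast is 2β₁ under every
model, the standard convention that makes powers comparable across
models.  The reference error law is a generalized extreme value
distribution with shape 0 (a Gumbel), location 0, scale d = 5,
**left-truncated at 0** (ε conditioned ≥ 0, inverse-CDF sampling), as
arises for survival-time-like traits; this truncation direction and the
score scale were fixed by calibrating simulated selection rates and
powers against their reference values, and both remain parameters.
Centered-t and untruncated GEV variants are provided.  Reference
design: n = 1500, β₀ = β₁ = 0.5, ξ = Φ⁻¹(0.90).

What the generator does *not* emulate: genotyping error, missingness
mechanisms, linkage disequilibrium between SNPs, population
stratification, or covariate confounding.  Passing simulations
therefore demonstrate calibration and power under clean sampling, not
robustness to those artifacts.  For observed covariates the package
offers OLS residualization (`residualize`) before testing — the
standard two-step used in practice — but no structured
stratification correction.

A master seed spawns independent per-cell substreams
(`numpy.random.SeedSequence.spawn`), so every experiment table is
reproducible and cells are mutually independent; the seed is recorded
in each output row.

## Problem sizes used in validation

The packaged checks run at the reference n = 1500 with replicate
counts chosen per quantity: 10,000 for selection rates and null
calibration, 2,000 for α* means, empirical size and power cells,
20,000 for the 0.001-level size (a ~0.0008 probability needs the extra
precision), 30,000 at n = 600 for the plug-in moment consistency check
(the weakest covariance term has ~2% relative Monte-Carlo error at that
count, comfortably inside the 5% tolerance being asserted), and 1,000
per cell for the 27-cell robustness grid.

## Known limitations

* Asymptotic reference laws throughout; no exact small-sample nulls.
  Group sizes below ~20 deserve the permutation MAX3 rather than the
  normal approximation.
* Two-sided tests only, matching the |Z| rejection regions the size
  adjustment assumes; one-sided variants are not implemented.
* Per-SNP analysis: no multiplicity correction across SNPs is applied —
  users supply their own genome-wide threshold, which
  `adjusted_threshold` converts to a per-SNP α*.
* The additive-weight variability ignored in ρ̂_A is O(n⁻¹); at the
  sample sizes the procedure targets (hundreds and up) it is
  negligible, but very small cohorts may see mild miscalibration.
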