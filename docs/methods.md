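# Methods

This note documents the models, algorithms and numerical choices behind
`gardenring`, and what its synthetic-data tests do and do not establish
about real provenance-trial data.

## Soil moisture index

Monthly bucket water balance. The store W (mm) obeys

    W_m = clamp(W_{m-1} + P_m − AET_m, 0, w_max),
    AET_m = PET_m · g(W_{m-1}),
    g(W)  = (W/w_crit)(2 − W/w_crit)  for W < w_crit, else 1.

PET uses a simplified Penman–Monteith closed form driven by monthly
mean temperature and vapour-pressure deficit,
`PET = 93 · VPD · exp(T/23.88)` mm per month (canopy and aerodynamic
terms folded into the constants), zero for frozen months. SMI is
reported as 100·W/w_max.

Defaults `w_max = 300 mm`, `w_crit = 400 mm`. Because w_crit exceeds
w_max, the drawdown never leaves the quadratic regime; this apparent
oddity is kept deliberately as the trial's stated parameterization.
Winter precipitation (months with T < 0 °C) accumulates in a snowpack
released at the first month above freezing (toggleable; the underlying
formulation does not specify snow handling). The initial store defaults
to a full bucket and is logged; the spin-up year before the analysis
window absorbs most of its influence. Mass balance closes to machine
precision (tested), and AET is additionally capped at the water
actually present within a month.

Drought events are flagged from summer (JJA) anomaly ratios — yearly
summer mean over the baseline-period summer mean. A year is an event
year when its ratio falls below a quantile of all years (default 0.15)
*and* below an absolute ceiling (default 0.9); the ceiling stops the
quantile rule from always nominating the driest years of an
unremarkable record. Consecutive flagged years merge into one event
dated at the final year, so a two-year episode like 2001–2002 is
indexed at 2002.

## Ring-level traits

BAI assumes circular stems with radii cumulated from the pith outward
(R_t = Σ RW). Lumen diameters are LDr = TDr − CWT, LDt = TDt − CWT;
conduit wall reinforcement uses the double-wall convention
CWR = (2·CWT/LD)², exposed as a config option (`wall="single"` drops
the factor 2) because the single/double convention varies across the
wood-anatomy literature. The cross-dating screen is a deliberately
simplified surrogate for full segment-wise dating software: it
correlates each prewhitened series against a leave-one-out prewhitened
master, flags series below r = 0.32 and reports the best lag within
±3 yr.

## Two-step standardization

Step 1 fits a penalized additive model (cubic B-splines, one smooth per
covariate: cambial age, cumulated basal area, competition) by GCV via
statsmodels' GAM machinery. On tables above ~4000 rows the smoothing
parameters are searched on a random subsample and rescaled
proportionally to n; the final fit always uses the full table.
Residuals are response-scale. The competition index is Hegyi-type,
Σ_j (size_j/size_i)/d_ij over neighbours within 3.6 m, computed from
planting coordinates (1.2 m within rows, 2.4 m between rows); the
original study's exact competition formula is in inaccessible
supplementary material, so this standard index is a documented
substitute.

Step 2 prewhitens each tree's residual series with an AR(p) model,
p ≤ 3 chosen by conditional-likelihood AIC on a common sample;
non-stationary fits fall back to p−1. Innovations are mean-centred and
rescaled to the input variance. Chronology years before 1989 are cut
(juvenile growth; configurable).

## Dendroclimatic correlations

Static Pearson correlations between residual chronologies and each of
the 18 monthly slots May(t−1)–Oct(t). Significance comes from a
stationary bootstrap over years (geometric block lengths, mean 4 yr,
1000 draws, seeded) — flagged when the 95% percentile interval excludes
zero — and a parametric t-test flag is emitted alongside, since which
of the two a published dot represents is often ambiguous.

## REML engine

The provenance-trial models are Gaussian mixed models with crossed and
nested random factors and, for the repeated-measures model, a residual
that is AR1 or ARH1 across the 11 annual measurements within a tree
(Cov(e_s, e_t) = σ_s σ_t ρ^{|s−t|}). No installed library fits this
combination, so the engine is built here on the mixed-model-equations
identity

    −2 l_R = (n−p) log 2π + log|R| + log|G| + log|C| + y'Py,

with C the sparse MME coefficient matrix. The AR1 block inverse is
tridiagonal, so W'R⁻¹W for W = [X | Z | y] is assembled at each step as
a weighted sum of a handful of precomputed sparse Gram matrices (split
by year for ARH1); log|C| and the quadratic form come from a sparse LU
factorization. The identity was validated against a brute-force dense
GLS REML computation to machine precision for all three residual
structures, and against the closed-form balanced one-way ANOVA
estimators to 1e−6.

Numerics: variances are optimized as log σ² and the correlation as
atanh ρ (L-BFGS-B, bounds 1e−8·var(y) to 1e4·var(y), |ρ| ≤ 0.98),
from three documented start points by default; estimates at the lower
bound are flagged as boundary. Fixed-effect design matrices are
treatment-coded and pruned to full rank by pivoted QR (the year main
effect inside block-nested-in-year dummies, for example). Trees with
non-contiguous year series are rejected rather than imputed — gaps in a
ring series indicate dating problems, and the AR1 inverse would lose
its banded form.

The asymptotic covariance of the variance estimates is the inverse
observed information, computed as a central finite-difference Hessian
of −l_R with respect to the natural-scale parameters at the optimum
(relative step 1e−3); it feeds the delta-method SEs of the ratios.
Random-term significance uses the REML likelihood-ratio statistic
against the 0.5·χ²₀ + 0.5·χ²₁ boundary mixture.

## Heritability and Q_ST

With within-family relatedness r, the additive variance is
σ̂²_A = σ̂²_fam/r, hence

    h²   = (1/r) σ̂²_fam / σ̂²_p,
    Q_ST = σ̂²_pop / (σ̂²_pop + 2 σ̂²_fam / r),

where σ̂²_p sums family, family-by-year, plot and residual components
(year-specific plot and residual variances averaged across years). The
alternative literal placement of r in the Q_ST denominator
(2·r·σ̂²_fam) is rejected: it is inconsistent with half-sib theory and
cannot reproduce the reported ratios (unit-tested). r defaults to the
realized genomic value 0.2573 rather than the pedigree 0.25, because
open pollination lets some families contain full sibs.

The G-matrix is VanRaden method 1, G = WW'/(2Σp(1−p)), with per-SNP
mean imputation of missing genotypes and monomorphic SNPs dropped; r̂
is the mean off-diagonal entry over within-family pairs. F_ST is
Weir–Cockerham θ per SNP with the overall value by ratio of sums;
Nei-style G_ST is emitted alongside as a cross-check (it carries no
sample-size correction and runs higher at small deme sizes, so the two
are expected to differ).

Note on relatedness under population structure: with provenances at
F ≈ 0.043, within-family VanRaden relationships include provenance-
level co-ancestry and average ≈ 0.32 rather than the pedigree 0.25; the
pedigree expectation is isolated by the panmictic half-sib simulation
used in the tests.

## Clinal analysis

Adaptive hinge-basis regression on provenance means: the forward pass
adds mirrored hinge pairs max(0, x−k)/max(0, k−x) (optionally times an
existing term, interactions capped at degree 2, knots at observed
values excluding endpoints) up to 21 terms; the backward pass prunes by
GCV with cost-per-term C(M) = M + d(M−1)/2, d = 3 with interactions and
2 without — the canonical defaults, both exposed. Predictors are
standardized internally, making the fit affine-invariant; knots are
reported in original units. Response surfaces flag grid cells outside
the convex hull of the observed predictor pairs as extrapolation.

The published 57.1% variance explained for 2002 resilience cannot be
checked without the access-restricted phenotypes; the tests instead
verify exact-function recovery, the GCV pruning property, nesting of
the linear case, and that the surface gradient on synthetic clinal data
carries the generating signs.

## Synthetic common garden

The generator reproduces the trial's structure: 43 provenances carrying
one to five half-sib families each (197 total), six randomized complete
blocks of five-tree row plots (1.2 m × 2.4 m spacing), 1481 cored trees
sampled from the 5910 planted, ring years 1979–2007, droughts imposed
in 1997, 2001–2002 and 2005 (precipitation severity multipliers 0.5,
0.5/0.45, 0.55), and 6386 SNPs drawn from a Balding–Nichols model at
F = 0.043 with explicit maternal alleles so genomic and pedigree
relatedness can disagree realistically.

Weather: seasonal sinusoid temperatures with AR(1) anomalies
(φ = 0.7), two-state Markov precipitation occurrence (p_wd = 0.30,
p_ww = 0.60) with gamma amounts (mean 6.4 mm/wet day, shape 0.7 —
roughly 1000 mm yr⁻¹, matching the wetter half of the origin gradient),
RH tied negatively to temperature anomalies and VPD derived from the
Tetens saturation curve. Drought years scale June–September amounts and
add a temperature bump and RH drop proportional to 1 − severity.

Log ring width is

    log RW = age trend (a + b·log age − c·age)
           + sens_i · z_t + resil_f · w_rec(t)
           + u_pop + u_fam + u_plot + u_pop:year + u_fam:year
           + AR(ρ) residual,

with z_t the summer-SMI z-score (drought years get extra imposed stress
proportional to 1 − severity), sens_i a provenance climate sensitivity
increasing with origin summer moisture and temperature, and resil_f a
family-level post-drought recovery effect (lag-1/lag-2 weights 1.0/0.5
scaled by 1 − severity) *decreasing* with origin summer moisture and
temperature. Two separate channels are necessary: family and provenance
main effects cancel exactly in the resilience ratios, and because the
2001 drought sits inside the 2002 pre-drought window, a climate-
sensitivity gradient alone acts on resilience with the opposite sign
(sensitive provenances have a more depressed pre-window). The recovery
slope (0.02 per SMI %) is set to dominate that window artifact, so the
generator genuinely encodes "drier origins are more resilient"; its
family-level spread (SD 0.05) is what makes the drought-resilience
traits heritable. Variance-component defaults (σ²_pop = 0.008,
σ²_fam = 0.005, σ²_plot = 0.05, σ²_pop:year = 0.01, σ²_fam:year = 0.02,
σ²_e = 0.23, ρ = 0.5) were chosen so the log-scale phenotypic variance
matches the reported growth analysis (~0.30).

What the generator does **not** emulate: spatial autocorrelation of
microsite quality beyond the plot term, linkage disequilibrium and
selection at individual SNPs, measurement error structure of X-ray
densitometry, cross-dating errors, or mortality/missing-ring patterns.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to those real-data complications.

## Problem sizes in the test suite

Parameter-recovery suites run at the trial's structural scale but with
reduced replication chosen for single-CPU runtimes: the repeated-
measures REML recovery uses 43 provenances × 2 families × 6 blocks ×
1 tree/plot over 11 years (20 seeds; medians within 15%), and the
Q_ST-recovery experiment uses the full 197 families at 1 tree/plot
(10 seeds, clinal links disabled so σ²_pop alone controls the truth).
With one tree per plot the plot variance is unidentifiable and is set
to zero rather than estimated. Marker suites use 5000 SNPs and 20–43
demes. The full-size generator (5910 planted, 1481 cored trees) is
exercised directly in the clinal and drought-detection checks, where no
REML fit is needed.

## Known limitations

* ARH1 with many years multiplies optimizer dimensions; for short
  series (< 4 years per tree) fall back to AR1 or independent
  residuals, which the model spec exposes directly.
* The delta-method CIs are symmetric and can cross the natural [0, 1]
  bounds of ratio parameters near boundaries, exactly as reported
  ratio CIs sometimes do; no transformation is applied.
* The finite-difference observed information can be indefinite when a
  component sits on the zero boundary; boundary estimates are flagged
  and their SEs should be read with caution.
* GCV-selected smoothing in the detrending step is searched on a
  subsample for large tables; the ~n rescaling of the penalty is a
  heuristic, adequate because only the residuals (not the smooths
  themselves) propagate downstream.
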