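# Methods

## Growth model and estimation

The trajectory h(x) = θ₁(e^{θ₂x} − 1) is the sapling-stage limb of a
Chapman–Richards curve: below ~25 years the sigmoid's asymptotic bend has
not set in and the exponential form is indistinguishable from the full
curve. θ₁ (m) sets the height scale a site's climate supports; θ₂ (1/yr)
is the relative growth rate. Both are linear in scaled climate: all
degree-day and evaporation variables are divided by 100 at ingestion so
coefficients are of order 1 (MAT, already of order 1 in °C, is never
scaled). The curve passes through the origin by construction, and the
model is restricted to sites with annual DD5 > 100 degree-days (below
that there is effectively no growing season and the fitted climate
functions extrapolate meaninglessly); violations raise
`ApplicabilityError` rather than returning numbers.

Errors are assumed i.i.d. Gaussian with constant variance. Under that
error structure — one equation, equal variances, zero covariances —
full-information maximum likelihood coincides with nonlinear least
squares, which is how the fit is implemented: multi-start trust-region
least squares (`scipy.optimize.least_squares`, ftol/xtol/gtol 1e-12),
with starting values from a pooled climate-free exponential fit and all
climate coefficients at zero, plus jittered copies of that start. The
implementation was cross-checked against R's `minpack.lm::nlsLM` on a
synthetic dataset: coefficients and standard errors agree to six decimal
places.

Fit statistics follow the nonlinear-regression conventions: pseudo
R² = 1 − SSE/SST_corrected; RMSE = √(SSE/(n − p)); AIC =
n[ln 2π + ln(SSE/n) + 1] + 2p with p counting both intercepts and all
climate coefficients. A zero-SSE fit is reported with the `perfect_fit`
flag and AIC = −∞. Standard errors come from the Gauss–Newton covariance
(JᵀJ)⁻¹s²; on 200 simulated refits at the study scale their 2-SE
coverage is 0.94 (z-scores have sd ≈ 1.07, the usual mild finite-sample
optimism of nonlinear LS; a full-Hessian observed-information variant was
tried and does not improve calibration, so the standard form is kept).
Negative fitted θ₁ or θ₂ anywhere in the data's climate range is
permitted — signs are not constrained — but flagged in `warnings`.

Scenario analysis uses the closed forms: acceleration h″ = θ₁θ₂²e^{θ₂x}
and cumulative growth ∫h = θ₁/θ₂(e^{θ₂b} − e^{θ₂a}) − θ₁(b − a), with a
series limit below |θ₂| = 1e-8 where the ratio form loses precision.

## Subset search

θ₁ being climate-dependent makes the log-linearization shift ambiguous;
the pooled (climate-free) θ̂₁ is the only single "θ₁ unit" available
before climate fitting, so the response is ln(h + θ̂₁). Each subset's
variables enter both the intercept block (acting on ln θ₁) and an
age-interaction block (acting on θ₂), alongside age itself; the subset
controls availability, OLS controls magnitude, and the count of candidate
models is exactly 2¹². AIC uses p = 2 + 2k for a k-variable subset. Ties
rank smaller subsets first, then lexicographically. The search is a
screening device only: selected specifications are refit with the full
nonlinear estimator. The ΔAIC > 2 rule (strict) decides whether a
candidate meaningfully improves on a base model.

## PLSR screening

Single-response NIPALS PLSR (scikit-learn backend) with internal
standardization. Loadings are reported as Pearson correlations between
each variable and the component scores — the scale on which the 0.4
selection cutoff operates; selection takes |loading| ≥ cutoff on any
retained component, so negatively loading variables are eligible.
Component count is chosen by leave-one-out cross-validation: the smallest
k whose successor improves RMSEP by no more than 2% *of the mean-only
(null) RMSEP*. Normalizing by the null scale rather than the current
RMSEP keeps the rule stable when RMSEP approaches zero. The module is
pool-agnostic; a synthetic pool generator emulates the collinear-block
structure of downscaled climate pools (informative variables sharing a
latent factor) for testing. Real pools have richer correlation structure
(seasonal nesting, elevation gradients) that the generator does not
attempt, so passing tests demonstrate the mechanics of screening, not its
field error rates.

## Cross-validation

Folds are stratified by species — unstratified folds can leave a species
entirely out of training, making its out-of-fold predictions an
extrapolation the analysis never intends — and shuffled by a recorded
seed. The niche model is refit from scratch on each training split
(the standard reading of k-fold CV); per-species and overall bias
(mean(obs − pred); positive = underestimation) and RMSE (√mean squared,
i.e. the n-denominator form, distinct from the fit-report's n − p form)
use out-of-fold predictions only. A fold whose refit fails to converge is
flagged, never silently dropped.

## Inventory-plot pipeline

Order is fixed: filter (conifer fraction ≥ 0.70, inclusive) → average
repeated samplings per plot → attach predicted height at the standard age
of 8 years. Productivity classes are an inverted ordinal (1 = most
productive); they are recoded to the midpoints of their cubic-feet/acre/
year ranges (class 1, open-ended at 225+, is set to 250) before
correlating, so a positive r means "taller where more productive".
Pearson correlation is used throughout, including on count and ordinal
responses, with the slope F-test on (1, n − 2) df always derived from the
retained n. The 95% trim keeps points with both coordinates within their
variable's mean ± 2 sd; a zero-sd coordinate retains exactly the points
at the mean. Regression lines (slope/intercept) are withheld from the
output table when p ≥ 0.05.

## Synthetic generators

The provenance generator draws the study conditions: 616 populations of
15 species, integer ages uniform on 1–25, climates uniform and
independent over Pacific-Northwest-plausible ranges (a Gaussian-copula
correlation matrix is optional; independence is the default because the
variable-dominance analyses are only well-posed without confounding), and
heights from the published annual-variable coefficient set plus N(0,
0.65²) noise — 0.65 m matching the reported overall cross-validated error
scale — floored at zero. Species labelled adaptive specialists (fraction
0.4 of species by default) receive an extra 0.35 m of noise in
quadrature, emulating the larger residuals observed for specialist
conifers without asserting a mechanism. Default climate ranges — Eref
450–950 mm, DD5 400–2,400, DD_18 3,000–4,800 degree-days, plus seasonal
splits — were chosen by forward simulation to keep θ₁ positive across
the whole range, reproduce the reported ~0.46–4.77 m span of predicted
age-8 heights, and give a pooled climate-free exponential fit R² near
0.9, the scale reported for the compiled trial data. These are design
constants, not fitting targets.

The inventory-plot generator draws a climate vector per plot, computes
predicted height at age 8, and couples productivity, biomass and
diversity to it through a Gaussian copula whose target correlations
default to the observed height–ecosystem-function values (+0.282
productivity, +0.162 biomass, −0.022 tree diversity, +0.080 species
diversity, with tree-diversity couplings +0.255/+0.158 to productivity/
biomass and +0.5 productivity–biomass). Marginals: 7 ordinal productivity
classes, lognormal biomass, tree diversity on 1–8 with half the mass at
≤ 2 (sample median ≈ 2.5), shifted-geometric species counts, Beta(8, 1)
conifer fraction (≈ 6% of plots below the 0.70 threshold, so filtering is
always exercised). Discretization attenuates the realized correlations
slightly relative to the latent targets; tests therefore check signs and
rough magnitudes, not exact values. What the generators do not emulate:
geography and spatial autocorrelation, inter-variable climate correlation
(by default), age-dependent error variance, and tree-level measurement
structure — so green tests certify the statistical machinery, not
field-data performance.

## Problem sizes and determinism

Tests and the acceptance script run at the study's own scale (616
populations, 4,096 subsets, 10 folds) or below; the plot pipeline is
exercised at 6,000–8,000 plots in tests while the generator default
remains 44,000. All stochastic steps take explicit integer seeds;
`derive_seeds` expands one root seed into reproducible child seeds via
`numpy.random.SeedSequence`, and the CLI splits one root seed
deterministically per stage. Reported coefficient-recovery values average
20 seeded refits, whose mean has a measured relative error ≤ ~2% against
the generating coefficients.

## Known limitations

- The exponential form is wrong past the sapling stage; no asymptote is
  fitted and ages > 25 are rejected at the data model.
- The censoring introduced by flooring heights at zero is ignored by the
  Gaussian fit; at the default noise level ~4% of records are affected
  and the induced coefficient bias is below 0.25 SE.
- The log-linearized search shares one shift θ̂₁ across all subsets; it
  ranks specifications well but its coefficient estimates are not the
  final ones.
- PLSR is single-response NIPALS only; no VIP scores, no multi-response.
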