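# Methods

## The model

`growthspurt` fits the SITAR (SuperImposition by Translation And
Rotation) shape-invariant growth model to mixed-longitudinal height
data.  Height of subject *i* at decimal age *t* is

```
h_it = g(x_it) + αᵢ + e_it,
x_it = x₀ + (t − x₀ − b₀ − βᵢ) · exp(c₀ + γᵢ),
```

where

* `g` is a natural cubic spline (population mean height curve, intercept
  included), with `df` basis columns, interior knots at equally spaced
  quantiles of the observed ages and boundary knots at the age range
  limits; beyond the boundary knots the curve continues linearly;
* `x₀` is a fixed age offset (the mean observation age) about which the
  age axis is stretched — centering the stretch decorrelates the tempo
  and velocity effects;
* `(αᵢ, βᵢ, γᵢ)` are zero-mean trivariate-normal random effects: **size**
  (cm, vertical shift), **tempo** (years; larger β = later spurt) and
  **velocity** (log age-scale factor; positive γ = compressed age scale =
  steeper, shorter spurt with peak velocity scaled by e^γ);
* `b₀, c₀` are fixed offsets that absorb the random-effect means, so the
  reported effects are exactly centered;
* `e_it` is homoscedastic Gaussian noise (SD `residual_sd`).

Velocity and acceleration are analytic derivatives of the fitted curve:
`v(t) = e^{c₀+γ} g'(x)` and `a(t) = e^{2(c₀+γ)} g''(x)`.

A note on conventions: the age transform is sometimes written with the
velocity factor applied to the tempo shift only (β·e^{−γ}); we use the
canonical form above, in which both conventions coincide at γ = 0 and
differ only by a reparameterisation of β.

## Estimation

Approximate maximum likelihood by alternating optimisation:

1. **Spline step** — given the random effects, the spline coefficients
   and intercept solve a linear least-squares problem on transformed ages.
2. **Subject step** — given the mean curve, each subject's `(α, β, γ)`
   maximises its penalised (shrunken) Gaussian log-likelihood by damped
   Gauss–Newton with an analytic residual Jacobian; steps are accepted
   only when the objective improves.
3. **Centering** — component means of the random effects move into
   `(intercept, b₀, c₀)`; this leaves every prediction unchanged and
   never decreases the likelihood.
4. **Variance step** — a Laplace EM update: the residual variance and the
   3×3 random-effect covariance are updated from posterior modes *plus*
   posterior covariances (the Laplace analogue of the exact E-step).
   Using only the modes would shrink the covariance toward the sample
   covariance of shrunken estimates and bias it low.

The recorded log-likelihood trace is the Laplace approximation to the
marginal likelihood; it is non-decreasing across outer iterations up to
approximation error (tested at relative 1e-6).  Convergence is declared
when its relative change falls below `tol` (default 1e-6); the default
iteration cap is 200, and study-scale experiments in this repository run
with a cap of 600 because the EM tail converges linearly (typically
150–550 iterations at n ≈ 150 subjects, a few seconds to ~1 minute per
fit on one CPU).  Non-convergence is flagged, never silent.
Initialisation is deterministic (subject mean height minus grand mean
for α; zero tempo/velocity), so fits are reproducible without a seed.

Defaults: `df = 5` (user-overridable; the spline's flexibility, not the
subject count, limits what the velocity curve can resolve — see
Limitations), extrapolation guard band 0.25 y, subjects with fewer than
3 measurements dropped with a warning.

## Spurt parameter extraction

From each subject's fitted velocity curve `v(t)`:

* **APHV / PHV** — location and value of the maximum of `v` over the
  search window (default: the fitted curve's boundary-knot span).
* **AOGS / OGSV** — the takeoff, defined as the maximum of the
  acceleration `v'(t)` before APHV ("the point where the velocity curve
  rises most steeply"); OGSV is `v(AOGS)`.  We read "rises most steeply"
  as peak acceleration rather than peak jerk: it is the standard
  takeoff-as-maximum-acceleration operationalisation and needs only
  first derivatives of `v`.
* **end age / GSI** — the first age after APHV where `v` returns to
  OGSV; GSI = end − AOGS exactly.

Extrema are located by a 0.01-year grid scan refined by bounded scalar
minimisation to 1e-4 y; the end age by bracketing and bisection to
1e-4 y.  Monthly-resolution reporting therefore carries no numerical
search error.  Estimates on a window boundary, and end ages not reached
before the search limit, are flagged; flagged subjects are excluded from
cohort summaries with counts reported.

## Synthetic cohorts

The generator produces the study conditions the analysis assumes:

* **Template mean curve.** A *designed* piecewise-polynomial velocity
  curve (scipy `PPoly`): childhood decline to a pre-spurt nadir, a
  quartic onset whose acceleration maximum sits exactly at the target
  AOGS (zero jerk there), a quartic rise to the target APHV/PHV, a cubic
  descent reaching the target OGSV exactly one GSI after takeoff, and a
  tail to the adult plateau; height is the antiderivative anchored at
  the target adult height.  All six calibration targets hold exactly by
  construction and are re-verified through the same extraction machinery
  used on fitted subjects.

  Why not a classic parametric family?  Preece–Baines model 1 is
  implemented (`TemplateCurve`, `calibrate_pb1_template`) but its takeoff
  geometry is rigid: over its entire parameter range the
  maximum-acceleration takeoff sits at ≥ ~0.69 of peak velocity and the
  spurt interval near 1.8× the takeoff-to-peak spacing.  Reference
  curves derived from spline fits show takeoff at ~0.56–0.61 of peak and
  spurt intervals of ~3.6–3.7 y; those targets are unreachable in PB1,
  which can therefore only be calibrated to the (AOGS, APHV, PHV,
  adult height) subset.

* **Random effects.** Size SD 5 cm (a package choice on the usual
  height-SD scale; the reference value is unpublished), tempo SD equal
  to the reference APHV SD (0.69 y boys, 0.74 y girls), velocity SD set
  to the reference PHV coefficient of variation (0.1311 / 0.1310), and
  the reference correlation matrices (boys 0.09 / 0.33 / −0.43, girls
  0.18 / 0.29 / −0.36 for size–tempo / size–velocity / tempo–velocity).
  Because velocities scale by e^γ, generated velocity-type parameters
  have means inflated by the lognormal factor e^{σ_γ²/2} ≈ 1.009 — below
  one percent, but visible at n = 500.

* **Sampling design.** Nominal biannual visits at 7.25, 7.75, …, 16.25 y
  with uniform ±0.1 y jitter and independent per-visit missingness 0.30.
  This yields ~13 measurements per subject and lets ~92% of subjects
  pass the five-segment inclusion rule.  (At missingness 0.35 the
  expected pass rate drops to ~87%, below what the inclusion-rule
  experiments need, because the five segments contain only 3–4 nominal
  visits each.)

* **Noise.** Homoscedastic Gaussian, SD 0.78 cm (boys) and 0.71 cm
  (girls), pinned through the half-normal mean identity E|e| = σ√(2/π)
  to reference model MAEs of 0.62 and 0.57 cm.

* **Reproducibility.** One `numpy` generator per subject seeded as
  (cohort seed, subject index): subject *k* is bit-identical regardless
  of cohort size.

What the generator does **not** emulate: informative or visit-dependent
missingness, heteroscedastic or non-Gaussian measurement error, secular
trends, seasonality of growth, or non-Gaussian random effects.  Passing
recovery tests on these cohorts shows the pipeline recovers the model's
own data-generating process under realistic sampling — not that the
model is correct for any particular real population.

## Reporting conventions

Sample SD uses the n−1 denominator.  Centiles (3, 5, 10, 25, 50, 75, 90,
95, 97%) interpolate linearly between order statistics (quantile type 7).
Quintile contrasts take the ⌊0.2 n⌋ largest and smallest subjects by the
ranking parameter (stable sort; ties crossing the cut are noted in the
result) and use Welch's unequal-variance two-sample t-test, two-sided.
Pearson correlations carry two-sided p-values from the t transform with
n−2 df.  α = 0.05 is used only for flagging, never for filtering.  Sexes
are always analysed as separate strata.

## Study-scale experiment sizes

Recovery and acceptance experiments use n = 150 subjects per sex, seeds
{1, 2, 3} (five seeds for sign-structure checks), five-segment filter,
df = 5 — chosen to mirror a ~130–150 subject school cohort per sex.
Property and unit tests run at 30–80 subjects.

## Known limitations

* **Takeoff resolution at low df.**  The fitted acceleration of a df=5
  natural spline is piecewise linear with breaks at its four interior
  knots, so the takeoff (argmax of `v'`) snaps to a knot in transformed
  age.  With quantile knots on a near-uniform 7.25–16.25 y design the
  knots sit near 9.05, 10.85, 12.65 and 14.45 y: cohort-mean AOGS
  estimates land ~0.4–0.9 y from a true takeoff at 10.17 y (boys) or
  8.57 y (girls), OGSV is read off a later, faster part of the velocity
  curve, and GSI shrinks correspondingly (−0.6 to −1.0 y).  APHV and PHV
  are essentially unaffected (the fitted velocity is piecewise quadratic
  and its peak moves freely).  This is a resolution limit of the
  fit-then-differentiate-twice design, shared by any analysis that reads
  takeoff off a low-df spline velocity curve — including the reference
  analyses such cohorts report — not an artifact of this implementation.
  Knots every ~1 y (df ≈ 6–8 on this age span) would resolve takeoff
  near the reference values.
* The Laplace-EM likelihood is approximate; variance components at small
  n (< ~20 subjects) are unstable and a warning is issued.
* The model carries no covariates; stratification (by sex) is the only
  adjustment mechanism.
* Velocity outside the boundary knots is linear-tail extrapolation and
  unreliable beyond the guard band.
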