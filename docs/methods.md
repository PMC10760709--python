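# Methods

## Cost model

The package models the metabolic cost of overground walking per unit body
mass.  Three ingredients:

1. **Steady rate.** Ė(v) = a₀ + a₁v + a₂v² (W/kg, v in m/s).  Reference
   coefficients per population group (above-knee amputation: 4.97, −5.98,
   5.62; below-knee: 3.64, −2.19, 2.89; no amputation: 2.22, 0, 1.115) come
   from treadmill indirect-calorimetry studies and are shipped in
   `gaitcost.reference`.  a₀, a₂ > 0 is required so cost per distance is
   U-shaped; a₁ may be negative.
2. **Changing-speed cost.** A rest-to-rest bout is idealised as an
   instantaneous jump to a constant speed v and an instantaneous stop.  The
   kinetic-energy change v²/2 (per kg) is converted to metabolic energy by
   the reciprocal efficiencies of positive and negative muscle work
   (η₊ = 0.25, η₋ = 1.2, so k = 1/η₊ + 1/η₋ ≈ 4.83) and scaled by a
   dimensionless empirical factor a_change.  Gradual acceleration and
   deceleration phases are deliberately not modelled; this idealisation is
   known to understate the cost structure of very short bouts and is the
   main caveat on quantitative values of a_change.
3. **Turning cost.** On a circle of radius R at tangential speed v the
   steady rate gains a term a_turn·(v/R)², with a_turn in W/kg per (1/s)².

All costs are mass-normalised: subject mass is carried in the data schema
for fidelity but never enters any computation.  (The kinetic-energy term
uses m = 1 kg-normalised for the same reason.)

## Forward optima and numerical choices

* Straight bouts: minimising E_total(v) = Ė(v)·D/v + a_change·k·v²/2 gives
  the implicit equation a_change·k·v³/(a₀ − a₂v²) = D.  The left side is
  monotone increasing on (0, √(a₀/a₂)), so the root is bracketed and solved
  by bisection (absolute tolerance 1e-10 on v, vectorised over coefficient
  grids).  a_change = 0 is handled analytically (optimum √(a₀/a₂)).
* Circles: closed form v\* = √(a₀/(a₂ + a_turn/R²)).
* Both optima are invariant to a₁ and to rescaling all five coefficients by
  a common positive factor; both increase monotonically in D or R toward
  √(a₀/a₂).  The test suite checks the solvers against dense-grid
  minimisation (step 1e-5 m/s) on random coefficient sets.
* The "1% band" around an optimum (the speeds whose cost is within 1% of
  the minimum — the energy landscape is flat near the optimum, so wide
  bands are expected) is found by geometric bracket expansion plus
  bisection (tolerance 1e-10).  If the cost never rises above the threshold
  below a cap (default 10× the optimum), the band is reported open-ended.

## Inverse optimization

Free coefficients are estimated by minimising the mean squared error
between model-optimal and observed speeds, pooled over all straight and
circle trials of one amputation group (per-trial weighting, so conditions
with four repeats weigh twice those with two).  Version 1 frees
(a_change, a_turn); version 2 frees (a₂, a_change, a_turn).  a₀ and a₁ are
never fit: a₁ does not enter the optima, and the scale invariance makes a₀
an arbitrary normalisation.

The optimizer is Nelder-Mead on log-transformed coefficients (which
enforces positivity) restarted from five start points spanning the
validation grids; the best minimum is kept.  Identifiability is checked up
front: a_turn requires at least one circle trial, a_change at least one
straight trial.

Every fit is validated against a fine parameter grid (defaults: a_change
0–10 step 0.01, a_turn 0–20 step 0.02, a₂ 0.5–10 step 0.01; a coarse pass
at 10× the step followed by a fine pass around the incumbent).  Because
a_change only affects straight-bout predictions and a_turn only circle
predictions, the grid SSE separates as SSE(a₂, a_change, a_turn) =
SSE_s(a₂, a_change) + SSE_c(a₂, a_turn), and the exhaustive grid minimum
is computed exactly without materialising the 3-D product.  A fit is
`grid_validated` iff no grid point beats the optimizer (tolerance 1e-12);
an optimum outside the grid bounds (by more than one step) makes the
validation inconclusive with a warning rather than an error.

## Hypothesis testing

Trial speeds are derived as D/T (straight) and laps·2πR/T (circle), then
averaged within subject and condition; all comparisons are paired within
subject.  The pre-registered family is ten one-sided tests: 4 m, 6 m, 8 m,
10 m each vs the 23 m bout; a positive-slope test for the speed–distance
fit (4–10 m bouts only); 1 m, 2 m, 3 m circles each vs the 23 m bout; a
positive-slope test for the speed–radius fit; and prosthesis-out vs
prosthesis-in pooled over radii.  Bonferroni multiplies each raw p by 10
(capped at 1).  An eleventh test — the direction contrast restricted to
the above-knee group — is flagged post hoc exploratory.

The primary procedure is a non-parametric bootstrap resampling **subjects**
with replacement (the sampling unit that respects within-subject
correlation): p is the proportion of resampled mean differences ≤ 0 for
the one-sided alternative, floored at 1/n_boot so p is never exactly zero.
Default n_boot is 10⁵.  A `resample_unit="trials"` switch resamples the
finer per-trial differences instead (ignoring clustering) for sensitivity
analysis.  Paired t-tests accompany every bootstrap test; zero-variance
differences are flagged degenerate with p ∈ {0, 1} by sign.  For the slope
tests, the bootstrap resamples subjects and recomputes the fixed-effects
slope from per-subject within moments (Frisch–Waugh), with the OLS
one-sided p as the parametric analogue.

Linear fits use OLS with subject dummy intercepts (fixed effects, not
random effects — the estimator is deliberately simple and the study design
balanced); reported are the common slope, per-subject offsets, the
standard adjusted R² of the full model, and the one-sided slope p.

Calibration (checked in the test suite, seeded): under a simulated null
with 12 subjects the bootstrap's type-I error at α = 0.05 is ≈ 0.068 —
slightly anticonservative at this sample size, as expected for percentile
bootstrap tests — and the null p-value distribution is uniform to
Kolmogorov–Smirnov distance < 0.1.  These checks use 2000 replications
with 2000 resamples per test.

## Synthetic cohorts

The generator reproduces the study protocol: 12 subjects (7 above-knee,
5 below-knee), distances {4, 6, 8, 10, 23} m × 4 trials, radii {1, 2, 3} m
with {5, 4, 3} laps × 2 turning directions — 26 trials per subject, 312
total.  Condition speeds are the model optima for the subject's group,
multiplied by a lognormal subject factor (σ_subject, default 0.08) and
lognormal trial noise (σ_trial, default 0.04), magnitudes chosen so
across-subject coefficients of variation land in the 5–8% range typical of
preferred-speed cohorts; the true within-subject variability of the
original cohort is not published, so σ_trial is a plausible placeholder,
not an estimate.  An additive `direction_effect` (default 0) raises
prosthesis-out circle speeds.  Durations are back-computed from speeds, so
re-deriving speeds from the emitted tables is exact.  Subject covariates
are sampled uniformly within the original cohort's ranges and never
influence speeds.  A single seed drives everything via per-subject child
streams.

What passing tests on these cohorts show — and do not show: round trips
(generate → refit, inject → recover) validate the estimators and the
pipeline plumbing; they cannot validate the cost model against real
behaviour, because the generator *is* the model.  Summary statistics that
belong to the real measurements (the observed percent reductions of
17.2%/8.2%/30.2%, the observed slopes 0.015 and 0.09 s⁻¹) are reproduced
by the model-implied cohort only approximately (16.3%/6.0%/35.3%; 0.0164
and 0.157 s⁻¹): the model captures the direction and rough size of the
distance effect, but its speed–radius curve is steeper over 1–3 m than the
observed linear trend.  Analysing the real deposited data requires only
two CSVs in the documented schema (a column-mapping adapter and a
per-lap-duration switch are provided in `read_dataset`).

## Known limitations

* Instantaneous speed-up/slow-down idealisation (above).
* Inverse-optimized coefficients absorb any non-energetic costs (joint
  stress, stability, pain) that shape speed choice; they are effective,
  not purely metabolic, quantities.
* Fixed-effects linear fits and subject-level bootstrap assume the balanced
  repeated-measures design; strongly unbalanced data would warrant a
  mixed-effects treatment, which is out of scope.
* The no-amputation coefficient row is a literature reference used as a
  fixed comparison point; it is never refit.
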