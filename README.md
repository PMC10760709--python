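# gaitcost

Energy-optimality analysis of preferred walking speeds in users of passive
leg prostheses.

People choose lower walking speeds for short bouts and for tight turns.
`gaitcost` implements a metabolic cost model that explains both effects for
adults with unilateral below-knee (transtibial) or above-knee
(transfemoral) amputation, together with the statistical machinery to fit
and test it on timed walking-trial data: straight rest-to-rest bouts of
4–23 m and multi-lap circles of 1–3 m radius.

## The model

Steady walking at speed *v* costs a metabolic rate per unit body mass

> Ė(v) = a₀ + a₁v + a₂v²  (W/kg),

with group-specific coefficients from treadmill calorimetry literature.
A rest-to-rest bout of length *D* additionally pays a changing-speed cost —
the kinetic-energy change scaled by muscle work efficiencies (η₊ = 0.25,
η₋ = 1.2) and a dimensionless factor *a*_change:

> E_total(v) = Ė(v)·D/v + a_change·(1/η₊ + 1/η₋)·v²/2.

Minimising over *v* gives the implicit condition
a_change·v³(1/η₊ + 1/η₋)/(a₀ − a₂v²) = D, whose root (found by bisection)
rises with *D* toward √(a₀/a₂): shorter bouts → slower optimal speeds.
Walking a circle of radius *R* adds a turning rate a_turn·(v/R)², giving a
closed-form optimum v\* = √(a₀/(a₂ + a_turn/R²)): tighter circles → slower.

Inverse optimization runs this logic backwards: given observed preferred
speeds, estimate the coefficients whose cost minimum reproduces them, by
minimising the mean squared speed error pooled over straight and circle
trials.  Version 1 fits (a_change, a_turn) with the literature steady-rate
coefficients fixed; version 2 also frees a₂.  a₀ and a₁ are never fit — the
optima are invariant to a₁ and to rescaling all coefficients together.
Every fit is validated against an exhaustive fine parameter grid.

The statistics follow the study design: per-subject condition means,
percent speed reductions relative to the 23 m bout, ten pre-registered
one-sided paired tests (bootstrap with subject resampling, 10⁵ resamples,
paired t for comparison, Bonferroni ×10), and fixed-effects linear fits of
speed against distance or radius with subject-specific intercepts.  A
synthetic cohort generator reproduces the trial protocol (12 subjects,
5 distances × 4 trials, 3 radii × 2 turning directions) with lognormal
subject and trial variability, so the whole pipeline is testable without
any data download.

## Worked example

```python
import gaitcost as gc

coeffs = gc.reference.coefficients("above_knee", version=1)
eff = gc.EfficiencyParams()
print("v_opt(4 m)  =", round(gc.optimal_speed_straight(coeffs, eff, 4.0), 3))
print("v_opt(23 m) =", round(gc.optimal_speed_straight(coeffs, eff, 23.0), 3))
print("v_opt(R=1 m) =", round(gc.optimal_speed_circle(coeffs, 1.0), 3))

cohort = gc.generate_cohort(gc.SyntheticConfig(seed=7))
res = gc.PreferredSpeedModel.from_dataset(cohort, group="above_knee",
                                          version=1).fit()
print(res.summary())
```

prints

```
v_opt(4 m)  = 0.781
v_opt(23 m) = 0.901
v_opt(R=1 m) = 0.611
Inverse optimization of walking cost coefficients
====================================================
group:           above_knee
version:         1 (free: a_change, a_turn)
n trials:        182
MSE:             0.00905558 (m/s)^2
RMSE:            0.09516 m/s
grid validated:  True
----------------------------------------------------
coefficient     estimate  status
a0                4.9700  fixed
a1               -5.9800  fixed
a2                5.6200  fixed
a_change          1.8643  free
a_turn            6.3452  free
```

The forward predictions show the two signature effects: the optimal speed
for a 4 m bout (0.781 m/s) is well below the 23 m optimum (0.901 m/s), and
a 1 m circle is slower still (0.611 m/s).  The fit recovers changing-speed
and turning coefficients near the generator's values (1.86 vs 2.67 and
6.35 vs 7.71 here, displaced by the cohort's simulated noise at this seed),
with an RMSE of ~0.1 m/s and the optimum confirmed against the validation
grid.

The same analysis is available from the shell:

```sh
gaitcost simulate --seed 7 --out scratch/cohort
gaitcost report --subjects scratch/cohort/subjects.csv \
                --trials scratch/cohort/trials.csv --seed 7 --out scratch/run
```

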