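"""Synthetic cohort generator emulating the walking-trial protocol.

The generator reproduces the study design: each subject walks five straight
distances (4, 6, 8, 10, 23 m) four times each, and circles of radii 1, 2, 3 m
(5, 4, 3 laps) once per turning direction (prosthesis leg inside or outside
the circle) — 26 trials per subject, 20 straight + 6 circle.

Speeds are energy-optimal for the subject's amputation group under the cost
model, with multiplicative lognormal variability::

    v_ict = v_opt(condition c; group coefficients) * exp(b_i) * exp(e_ict)

where ``b_i ~ N(0, sigma_subject^2)`` is a persistent subject factor and
``e_ict ~ N(0, sigma_trial^2)`` is trial-to-trial noise.  An optional
additive ``direction_effect`` (m/s) raises prosthesis-out circle speeds, for
emulating a turning-direction asymmetry.  Durations are back-computed from
speeds (``T = D/v`` or ``laps * 2*pi*R / v``) so that re-deriving speeds from
the emitted table reproduces the generated speeds.

Multiplicative noise keeps durations positive, and the default magnitudes
(sigma_subject 0.08, sigma_trial 0.04) give across-subject coefficients of
variation in the 5-8% range typical of preferred-speed cohorts.  Subject
covariates (age, mass, heights, leg lengths, ...) are sampled uniformly
within the ranges of the study cohort for schema fidelity only; they never
influence the generated speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cost import CostCoefficients, EfficiencyParams, optimal_speed_straight, \
    optimal_speed_circle
from .data import CohortDataset, SUBJECT_COLUMNS, TRIAL_COLUMNS
from . import reference

__all__ = ["SubjectProfile", "SyntheticConfig", "generate_cohort",
           "make_fixture_suite"]


@dataclass(frozen=True)
class SubjectProfile:
    """One subject's covariates, mirroring the study's subject table."""

    subject_id: str
    age_yr: float
    mass_kg: float
    height_m: float
    leg_length_prosthesis_m: float
    leg_length_intact_m: float
    level: str  # "BK" or "AK"
    affected_side: str  # "L" or "R"
    sex: str  # "M" or "F"
    hours_on_legs_per_day: float
    years_since_amputation: float

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass must be positive")
        if self.level not in ("BK", "AK"):
            raise ValueError(f"level must be BK or AK, got {self.level!r}")
        for name in ("height_m", "leg_length_prosthesis_m", "leg_length_intact_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# covariate sampling ranges spanning the study cohort
_COVARIATE_RANGES = {
    "age_yr": (21, 60),
    "mass_kg": (47, 90),
    "height_m": (1.54, 1.84),
    "leg_length_m": (0.86, 1.07),
    "hours_on_legs_per_day": (1, 10),
    "years_since_amputation": (2, 30),
}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the study's trial design."""

    n_above_knee: int = 7
    n_below_knee: int = 5
    coeffs: dict[str, CostCoefficients] = field(
        default_factory=lambda: {
            "above_knee": reference.coefficients("above_knee", version=1),
            "below_knee": reference.coefficients("below_knee", version=1),
        }
    )
    eff: EfficiencyParams = field(default_factory=EfficiencyParams)
    sigma_subject: float = 0.08  # sd of log subject factor
    sigma_trial: float = 0.04  # sd of log trial noise
    direction_effect: float = 0.0  # additive m/s on prosthesis-out circles
    distances_m: tuple = (4.0, 6.0, 8.0, 10.0, 23.0)
    trials_per_distance: int = 4
    radii_m: tuple = (1.0, 2.0, 3.0)
    laps_per_radius: tuple = (5, 4, 3)
    directions: tuple = ("prosthesis_in", "prosthesis_out")
    constant_speed: float | None = None  # overrides the cost model (null cohort)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_subject < 0 or self.sigma_trial < 0:
            raise ValueError("noise sigmas must be non-negative")
        if len(self.radii_m) != len(self.laps_per_radius):
            raise ValueError("radii_m and laps_per_radius must align")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["coeffs"] = {g: asdict(c) for g, c in self.coeffs.items()}
        d["eff"] = asdict(self.eff)
        return d


def _draw_profile(rng: np.random.Generator, subject_id: str, level: str
                  ) -> SubjectProfile:
    r = _COVARIATE_RANGES
    return SubjectProfile(
        subject_id=subject_id,
        age_yr=float(np.round(rng.uniform(*r["age_yr"]))),
        mass_kg=float(np.round(rng.uniform(*r["mass_kg"]), 1)),
        height_m=float(np.round(rng.uniform(*r["height_m"]), 2)),
        leg_length_prosthesis_m=float(np.round(rng.uniform(*r["leg_length_m"]), 2)),
        leg_length_intact_m=float(np.round(rng.uniform(*r["leg_length_m"]), 2)),
        level=level,
        affected_side="R" if rng.uniform() < 0.25 else "L",
        sex="F" if rng.uniform() < 1.0 / 12.0 else "M",
        hours_on_legs_per_day=float(np.round(rng.uniform(*r["hours_on_legs_per_day"]))),
        years_since_amputation=float(np.round(rng.uniform(*r["years_since_amputation"]))),
    )


def _condition_speeds(config: SyntheticConfig, group: str) -> dict:
    """Noise-free target speed for every condition of one group."""
    if config.constant_speed is not None:
        v = config.constant_speed
        straight = {D: v for D in config.distances_m}
        circle = {R: v for R in config.radii_m}
        return {"straight": straight, "circle": circle}
    coeffs = config.coeffs[group]
    straight = {
        D: optimal_speed_straight(coeffs, config.eff, D)
        for D in config.distances_m
    }
    circle = {R: optimal_speed_circle(coeffs, R) for R in config.radii_m}
    return {"straight": straight, "circle": circle}


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Generate one synthetic cohort under ``config``.

    A single global seed drives everything; each subject gets an
    independent child stream so cohorts are reproducible and subjects are
    statistically independent.
    """
    n_total = config.n_above_knee + config.n_below_knee
    seq = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in seq.spawn(n_total)]
    levels = ["AK"] * config.n_above_knee + ["BK"] * config.n_below_knee
    group_of = {"AK": "above_knee", "BK": "below_knee"}
    target = {g: _condition_speeds(config, g)
              for g in {group_of[lv] for lv in levels}}

    subject_rows, trial_rows = [], []
    for i, (lv, rng) in enumerate(zip(levels, streams), start=1):
        sid = f"S{i:02d}"
        profile = _draw_profile(rng, sid, lv)
        subject_rows.append(asdict(profile))
        b_i = rng.normal(0.0, config.sigma_subject) if config.sigma_subject else 0.0
        speeds = target[group_of[lv]]

        for D in config.distances_m:
            for t in range(1, config.trials_per_distance + 1):
                e = rng.normal(0.0, config.sigma_trial) if config.sigma_trial else 0.0
                v = speeds["straight"][D] * np.exp(b_i + e)
                trial_rows.append(dict(
                    subject_id=sid, task="straight", trial_index=t,
                    distance_m=D, radius_m=np.nan, laps=np.nan,
                    direction=np.nan, duration_s=D / v,
                ))
        for R, laps in zip(config.radii_m, config.laps_per_radius):
            for direction in config.directions:
                e = rng.normal(0.0, config.sigma_trial) if config.sigma_trial else 0.0
                v = speeds["circle"][R] * np.exp(b_i + e)
                if direction == "prosthesis_out":
                    v = v + config.direction_effect
                if v <= 0:
                    raise ValueError(
                        f"non-positive generated speed for subject {sid}, "
                        f"R={R}, direction={direction} "
                        f"(direction_effect too negative)"
                    )
                trial_rows.append(dict(
                    subject_id=sid, task="circle", trial_index=1,
                    distance_m=np.nan, radius_m=R, laps=laps,
                    direction=direction, duration_s=laps * 2 * np.pi * R / v,
                ))

    subjects = pd.DataFrame(subject_rows)[SUBJECT_COLUMNS]
    trials = pd.DataFrame(trial_rows)[TRIAL_COLUMNS]
    return CohortDataset(
        subjects=subjects, trials=trials,
        provenance={"kind": "synthetic", "config": config.to_jsonable()},
    )


def make_fixture_suite(out_dir) -> dict[str, dict[str, Path]]:
    """Write the canonical synthetic fixtures used throughout the test suite.

    * ``noiseless`` — zero-noise cohort at the version-1 reference
      coefficients: every trial speed is exactly the group's model-optimal
      speed for its condition (inverse-optimization round trips recover the
      generating coefficients).
    * ``noisy`` — sigma_subject 0.08, sigma_trial 0.04, fixed seed.
    * ``null`` — constant target speed in every condition (no distance or
      radius dependence), for hypothesis-test calibration.

    Returns ``{fixture_name: {"subjects": path, "trials": path,
    "config": path}}``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = {
        "noiseless": SyntheticConfig(sigma_subject=0.0, sigma_trial=0.0,
                                     seed=20240102),
        "noisy": SyntheticConfig(sigma_subject=0.08, sigma_trial=0.04,
                                 seed=20240102),
        "null": SyntheticConfig(constant_speed=1.0, sigma_subject=0.08,
                                sigma_trial=0.05, seed=20240102),
    }
    paths: dict[str, dict[str, Path]] = {}
    for name, cfg in configs.items():
        cohort = generate_cohort(cfg)
        p = {
            "subjects": out / f"synthetic_{name}_subjects.csv",
            "trials": out / f"synthetic_{name}_trials.csv",
            "config": out / f"synthetic_{name}_config.json",
        }
        cohort.write(p["subjects"], p["trials"], p["config"])
        paths[name] = p
    return paths
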