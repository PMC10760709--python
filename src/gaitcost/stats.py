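"""Descriptive statistics and hypothesis tests for walking-speed cohorts.

Speeds are averaged within subject and condition first (trial counts differ
across conditions), and every comparison is paired within subject:

* percent speed reductions of each short distance / circle radius relative
  to the longest straight bout (23 m), summarised across subjects;
* one-sided paired tests — non-parametric bootstrap (resampling subjects
  with replacement) as the primary procedure, classical paired t-tests for
  comparison — with a Bonferroni correction over the 10 pre-registered
  tests;
* fixed-effects linear fits of speed against distance (short bouts only)
  or radius, with one intercept per subject to absorb between-subject speed
  differences.

The pre-registered battery is: four distance comparisons (4, 6, 8, 10 m vs
23 m), a positive-slope test for the speed-distance fit, three radius
comparisons (1, 2, 3 m circles vs the 23 m straight bout), a positive-slope
test for the speed-radius fit, and one prosthesis-in vs prosthesis-out
comparison pooled over radii — ten tests.  An eleventh, flagged post hoc
exploratory, repeats the direction comparison in the above-knee group only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .data import CohortDataset

__all__ = [
    "TestResult",
    "LinearFitResult",
    "ConditionMeans",
    "subject_condition_means",
    "percent_reduction",
    "bootstrap_paired_onesided",
    "paired_t_onesided",
    "linear_fit_subject_offsets",
    "run_hypothesis_battery",
    "N_PREREGISTERED_TESTS",
]

#: family size for the Bonferroni correction
N_PREREGISTERED_TESTS = 10


@dataclass
class TestResult:
    """One hypothesis test.

    ``statistic`` is the mean paired difference in m/s (or the fitted slope
    in 1/s for the slope tests); ``direction`` describes the one-sided
    alternative.  ``p_bonferroni = min(1, n_family * p_raw)``.
    """

    name: str
    statistic: float | None
    p_raw: float | None
    p_bonferroni: float | None
    n_boot: int | None
    seed: int | None
    direction: str
    method: str = "bootstrap"
    n_subjects: int | None = None
    p_floor_applied: bool = False
    degenerate: bool = False
    post_hoc: bool = False
    skipped: bool = False
    skip_reason: str | None = None
    p_t_raw: float | None = None
    p_t_bonferroni: float | None = None

    def to_record(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__
                if k != "self"}


@dataclass
class LinearFitResult:
    """Fixed-effects linear fit speed = slope * predictor + offset_subject.

    ``p_slope`` is the one-sided (positive-slope alternative) p-value from
    the OLS t statistic; ``adjusted_r2`` is the standard adjusted R^2 of
    the full fixed-effects model.
    """

    slope: float
    subject_offsets: dict
    adjusted_r2: float
    p_slope: float
    conditions_used: tuple
    predictor: str
    n_obs: int

    def to_record(self) -> dict:
        return {
            "slope_per_s": self.slope,
            "adjusted_r2": self.adjusted_r2,
            "p_slope_onesided": self.p_slope,
            "conditions_used": list(self.conditions_used),
            "predictor": self.predictor,
            "n_obs": self.n_obs,
            "subject_offsets": {str(k): float(v)
                                for k, v in self.subject_offsets.items()},
        }


@dataclass
class ConditionMeans:
    """Per-subject, per-condition mean speeds.

    ``straight``: subjects x distances; ``circle``: subjects x radii pooled
    over direction; ``circle_by_direction``: tidy frame with a direction
    column.
    """

    straight: pd.DataFrame
    circle: pd.DataFrame
    circle_by_direction: pd.DataFrame


def subject_condition_means(dataset: CohortDataset) -> ConditionMeans:
    """Average trial speeds within subject and condition.

    Straight-bout speed is distance/duration per trial, then averaged over
    the repeats of each (subject, distance).  Circle speed is
    ``laps * 2*pi*R / duration`` per trial, kept per turning direction and
    also pooled per (subject, radius).
    """
    trials = dataset.trials
    bad = trials.index[~(trials["duration_s"] > 0)]
    if len(bad):
        raise ValueError(f"non-positive duration in trial rows {list(bad)}")
    straight = trials[trials["task"] == "straight"]
    circle = trials[trials["task"] == "circle"]
    s_means = (
        straight.groupby(["subject_id", "distance_m"])["speed_m_s"]
        .mean().unstack("distance_m")
    )
    c_means = (
        circle.groupby(["subject_id", "radius_m"])["speed_m_s"]
        .mean().unstack("radius_m")
    )
    c_dir = (
        circle.groupby(["subject_id", "radius_m", "direction"])["speed_m_s"]
        .mean().reset_index()
    )
    return ConditionMeans(straight=s_means, circle=c_means,
                          circle_by_direction=c_dir)


def _subject_pools(dataset: CohortDataset) -> dict[str, list]:
    g = dataset.group_of()
    return {
        "all": list(g.index),
        "below_knee": list(g.index[g == "below_knee"]),
        "above_knee": list(g.index[g == "above_knee"]),
    }


def percent_reduction(
    dataset: CohortDataset,
    task: str,
    value: float,
    baseline_distance: float = 23.0,
) -> pd.DataFrame:
    """Speed reduction of one condition relative to the long straight bout.

    Per subject: ``100 * (v_baseline - v_condition) / v_baseline`` where
    both speeds are subject-condition means; summarised as mean and sd
    across subjects, for the whole cohort and each amputation group.
    Subjects missing the baseline or the condition are excluded (warning
    via the returned ``n``).
    """
    means = subject_condition_means(dataset)
    base = means.straight[baseline_distance]
    cond = (means.straight if task == "straight" else means.circle)[value]
    joined = pd.concat({"base": base, "cond": cond}, axis=1).dropna()
    pct = 100.0 * (joined["base"] - joined["cond"]) / joined["base"]
    rows = {}
    for pool, ids in _subject_pools(dataset).items():
        vals = pct[pct.index.isin(ids)]
        rows[pool] = {
            "mean_pct": float(vals.mean()) if len(vals) else np.nan,
            "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else
            (0.0 if len(vals) == 1 else np.nan),
            "n": int(len(vals)),
        }
    return pd.DataFrame(rows).T


def bootstrap_paired_onesided(
    x,
    y,
    n_boot: int = 100_000,
    seed=None,
    name: str = "",
    direction: str = "y > x",
) -> TestResult:
    """Paired one-sided bootstrap test of the alternative ``mean(y - x) > 0``.

    Subjects are resampled with replacement ``n_boot`` times; the raw p is
    the proportion of resampled mean differences at or below zero, floored
    at ``1/n_boot`` when no resample is that small (so p is never exactly
    zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned by subject")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    d = y - x
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = d[idx].mean(axis=1)
    p = float(np.mean(means <= 0.0))
    floored = p == 0.0
    if floored:
        p = 1.0 / n_boot
    return TestResult(
        name=name,
        statistic=float(d.mean()),
        p_raw=p,
        p_bonferroni=min(1.0, N_PREREGISTERED_TESTS * p),
        n_boot=n_boot,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        direction=direction,
        method="bootstrap",
        n_subjects=n,
        p_floor_applied=floored,
    )


def paired_t_onesided(x, y, name: str = "", direction: str = "y > x"
                      ) -> TestResult:
    """Classical paired t-test of the alternative ``mean(y - x) > 0``.

    Zero variance of the differences is degenerate: p is 0 for a positive
    mean difference and 1 otherwise, and the result is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    if np.allclose(d.std(ddof=1), 0.0):
        p = 0.0 if d.mean() > 0 else 1.0
        return TestResult(
            name=name, statistic=float(d.mean()), p_raw=p,
            p_bonferroni=min(1.0, N_PREREGISTERED_TESTS * p),
            n_boot=None, seed=None, direction=direction, method="t",
            n_subjects=len(x), degenerate=True,
        )
    res = sps.ttest_rel(y, x, alternative="greater")
    p = float(res.pvalue)
    return TestResult(
        name=name, statistic=float(d.mean()), p_raw=p,
        p_bonferroni=min(1.0, N_PREREGISTERED_TESTS * p),
        n_boot=None, seed=None, direction=direction, method="t",
        n_subjects=len(x),
    )


def linear_fit_subject_offsets(
    records: pd.DataFrame,
    predictor: str,
) -> LinearFitResult:
    """Least-squares fit of speed on a predictor with subject intercepts.

    ``records`` needs columns ``subject_id``, ``predictor`` (distance_m or
    radius_m) and ``speed_m_s``.  Subject intercepts are fixed effects
    (dummy variables); a subject with a single record contributes only its
    offset.  Requires at least two distinct predictor values.
    """
    df = records.rename(columns={predictor: "x"})[
        ["subject_id", "x", "speed_m_s"]
    ].dropna()
    values = np.sort(df["x"].unique())
    if len(values) < 2:
        raise ValueError("need at least 2 distinct predictor values")
    model = smf.ols("speed_m_s ~ x + C(subject_id)", data=df).fit()
    slope = float(model.params["x"])
    t = float(model.tvalues["x"])
    p_one_sided = float(sps.t.sf(t, df=model.df_resid))
    base = float(model.params["Intercept"])
    offsets = {}
    for sid in df["subject_id"].unique():
        key = f"C(subject_id)[T.{sid}]"
        offsets[sid] = base + float(model.params.get(key, 0.0))
    return LinearFitResult(
        slope=slope,
        subject_offsets=offsets,
        adjusted_r2=float(model.rsquared_adj),
        p_slope=p_one_sided,
        conditions_used=tuple(values),
        predictor=predictor,
        n_obs=int(model.nobs),
    )


def _within_subject_moments(df: pd.DataFrame):
    """Per-subject within moments (Sxx_i, Sxy_i) for the fixed-effects slope.

    With subject dummies, the OLS slope is sum_i Sxy_i / sum_i Sxx_i where
    the moments use within-subject demeaned predictor and speed
    (Frisch-Waugh).  Resampling subjects only reweights these sums.
    """
    sxx, sxy = [], []
    for _, g in df.groupby("subject_id"):
        x = g["x"].to_numpy(float)
        y = g["speed_m_s"].to_numpy(float)
        xc = x - x.mean()
        sxx.append(float(xc @ xc))
        sxy.append(float(xc @ (y - y.mean())))
    return np.array(sxx), np.array(sxy)


def _bootstrap_slope_positive(
    records: pd.DataFrame, predictor: str, n_boot: int, seed, name: str
) -> TestResult:
    """Bootstrap (subject resampling) test that the fixed-effects slope > 0."""
    df = records.rename(columns={predictor: "x"})[
        ["subject_id", "x", "speed_m_s"]
    ].dropna()
    sxx, sxy = _within_subject_moments(df)
    n = len(sxx)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    slope = float(sxy.sum() / sxx.sum())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    den = sxx[idx].sum(axis=1)
    num = sxy[idx].sum(axis=1)
    ok = den > 0
    slopes = num[ok] / den[ok]
    p = float(np.mean(slopes <= 0.0)) if len(slopes) else 1.0
    floored = p == 0.0
    if floored:
        p = 1.0 / n_boot
    return TestResult(
        name=name, statistic=slope, p_raw=p,
        p_bonferroni=min(1.0, N_PREREGISTERED_TESTS * p),
        n_boot=n_boot, seed=seed if isinstance(seed, (int, np.integer)) else None,
        direction="slope > 0", method="bootstrap", n_subjects=n,
        p_floor_applied=floored,
    )


def _direction_means(means: ConditionMeans, ids=None):
    """Per-subject mean speed for each turning direction, pooled over radii."""
    df = means.circle_by_direction
    if ids is not None:
        df = df[df["subject_id"].isin(ids)]
    pooled = df.groupby(["subject_id", "direction"])["speed_m_s"].mean().unstack()
    return pooled


def run_hypothesis_battery(
    dataset: CohortDataset,
    n_boot: int = 100_000,
    seed=None,
    resample_unit: str = "subjects",
    include_post_hoc: bool = True,
    distances=(4.0, 6.0, 8.0, 10.0),
    radii=(1.0, 2.0, 3.0),
    baseline_distance: float = 23.0,
) -> list[TestResult]:
    """Run the ten pre-registered one-sided tests (plus the post hoc
    above-knee direction test).

    Every bootstrap test draws its own child seed from ``seed`` so the
    battery is reproducible as a whole.  Each bootstrap result carries the
    matching paired-t p-values (or the OLS one-sided p for the slope tests)
    in ``p_t_raw`` / ``p_t_bonferroni``.  Missing conditions yield skipped
    records rather than errors.
    """
    if resample_unit not in ("subjects", "trials"):
        raise ValueError("resample_unit must be 'subjects' or 'trials'")
    means = subject_condition_means(dataset)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(12)]
    results: list[TestResult] = []

    def paired_test(x, y, child, name, direction, trial_d=None):
        """Bootstrap + paired-t on subject-condition means.

        With ``resample_unit='trials'`` and ``trial_d`` given, the bootstrap
        resamples the finer paired differences (one per trial or per
        subject-radius pair) instead of subjects, ignoring within-subject
        clustering; the reported statistic stays the subject-level mean
        difference.
        """
        if resample_unit == "trials" and trial_d is not None:
            d = np.asarray(trial_d, dtype=float)
            rng = np.random.default_rng(child)
            idx = rng.integers(0, len(d), size=(n_boot, len(d)))
            p = float(np.mean(d[idx].mean(axis=1) <= 0.0))
            floored = p == 0.0
            if floored:
                p = 1.0 / n_boot
            res = TestResult(
                name=name, statistic=float(np.mean(np.asarray(y) - np.asarray(x))),
                p_raw=p, p_bonferroni=min(1.0, N_PREREGISTERED_TESTS * p),
                n_boot=n_boot, seed=child, direction=direction,
                method="bootstrap(trials)", n_subjects=len(x),
                p_floor_applied=floored,
            )
        else:
            res = bootstrap_paired_onesided(
                x, y, n_boot=n_boot, seed=child, name=name, direction=direction
            )
        t = paired_t_onesided(x, y, name=name, direction=direction)
        res.p_t_raw = t.p_raw
        res.p_t_bonferroni = t.p_bonferroni
        return res

    def skipped(name, direction, reason):
        return TestResult(
            name=name, statistic=None, p_raw=None, p_bonferroni=None,
            n_boot=None, seed=None, direction=direction, skipped=True,
            skip_reason=reason,
        )

    base = means.straight.get(baseline_distance)
    # 1-4: each short distance slower than the long bout
    for i, D in enumerate(distances):
        name = f"speed({baseline_distance:g} m) > speed({D:g} m)"
        if base is None or D not in means.straight.columns:
            results.append(skipped(name, "y > x", f"missing distance {D}"))
            continue
        joined = pd.concat({"x": means.straight[D], "y": base}, axis=1).dropna()
        trial_d = None
        if resample_unit == "trials":
            t = dataset.trials
            rows = t[(t["task"] == "straight") & (t["distance_m"] == D)]
            trial_d = (base.reindex(rows["subject_id"]).to_numpy(float)
                       - rows["speed_m_s"].to_numpy(float))
        results.append(paired_test(joined["x"], joined["y"], child_seeds[i],
                                   name, "y > x", trial_d=trial_d))

    # 5: positive speed-distance slope over the short bouts
    short = dataset.trials[
        (dataset.trials["task"] == "straight")
        & dataset.trials["distance_m"].isin(distances)
    ]
    s_records = (
        short.groupby(["subject_id", "distance_m"])["speed_m_s"]
        .mean().reset_index()
    )
    name = "speed-distance slope > 0 (short bouts)"
    if s_records["distance_m"].nunique() >= 2:
        res = _bootstrap_slope_positive(s_records, "distance_m", n_boot,
                                        child_seeds[4], name)
        lin = linear_fit_subject_offsets(s_records, "distance_m")
        res.p_t_raw = lin.p_slope
        res.p_t_bonferroni = min(1.0, N_PREREGISTERED_TESTS * lin.p_slope)
        results.append(res)
    else:
        results.append(skipped(name, "slope > 0", "fewer than 2 distances"))

    # 6-8: each circle slower than the long straight bout
    for i, R in enumerate(radii):
        name = f"speed({baseline_distance:g} m straight) > speed(R={R:g} m)"
        if base is None or R not in means.circle.columns:
            results.append(skipped(name, "y > x", f"missing radius {R}"))
            continue
        joined = pd.concat({"x": means.circle[R], "y": base}, axis=1).dropna()
        trial_d = None
        if resample_unit == "trials":
            t = dataset.trials
            rows = t[(t["task"] == "circle") & (t["radius_m"] == R)]
            trial_d = (base.reindex(rows["subject_id"]).to_numpy(float)
                       - rows["speed_m_s"].to_numpy(float))
        results.append(paired_test(joined["x"], joined["y"],
                                   child_seeds[5 + i], name, "y > x",
                                   trial_d=trial_d))

    # 9: positive speed-radius slope
    c_records = (
        dataset.trials[dataset.trials["task"] == "circle"]
        .groupby(["subject_id", "radius_m"])["speed_m_s"].mean().reset_index()
    )
    name = "speed-radius slope > 0 (circles)"
    if c_records["radius_m"].nunique() >= 2:
        res = _bootstrap_slope_positive(c_records, "radius_m", n_boot,
                                        child_seeds[8], name)
        lin = linear_fit_subject_offsets(c_records, "radius_m")
        res.p_t_raw = lin.p_slope
        res.p_t_bonferroni = min(1.0, N_PREREGISTERED_TESTS * lin.p_slope)
        results.append(res)
    else:
        results.append(skipped(name, "slope > 0", "fewer than 2 radii"))

    # 10: prosthesis-out faster than prosthesis-in, pooled over radii
    name = "speed(prosthesis out) > speed(prosthesis in)"
    pooled = _direction_means(means)
    if {"prosthesis_in", "prosthesis_out"} <= set(pooled.columns):
        joined = pooled.dropna()
        trial_d = None
        if resample_unit == "trials":
            per_radius = means.circle_by_direction.pivot_table(
                index=["subject_id", "radius_m"], columns="direction",
                values="speed_m_s",
            ).dropna()
            trial_d = (per_radius["prosthesis_out"]
                       - per_radius["prosthesis_in"]).to_numpy(float)
        results.append(paired_test(joined["prosthesis_in"],
                                   joined["prosthesis_out"],
                                   child_seeds[9], name, "y > x",
                                   trial_d=trial_d))
    else:
        results.append(skipped(name, "y > x", "missing a turning direction"))

    # post hoc exploratory: direction contrast in the above-knee group only
    if include_post_hoc:
        name = "speed(prosthesis out) > speed(prosthesis in), above-knee only"
        ak = dataset.subjects_in_group("above_knee")
        pooled = _direction_means(means, ids=ak)
        if len(pooled) >= 2 and \
                {"prosthesis_in", "prosthesis_out"} <= set(pooled.columns):
            joined = pooled.dropna()
            res = paired_test(joined["prosthesis_in"],
                              joined["prosthesis_out"],
                              child_seeds[10], name, "y > x")
            res.post_hoc = True
            results.append(res)
        else:
            rec = skipped(name, "y > x", "fewer than 2 above-knee subjects")
            rec.post_hoc = True
            results.append(rec)
    return results
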