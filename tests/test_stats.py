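"""Descriptive statistics, paired tests, and fixed-effects linear fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import gaitcost as gc
from gaitcost.data import CohortDataset
from gaitcost.stats import _bootstrap_slope_positive


def tiny_cohort(straight_rows, circle_rows=(), levels=("BK", "AK")):
    """Hand-built cohort; rows are (subject, D, trial_index, duration) for
    straight and (subject, R, laps, direction, duration) for circles."""
    sids = sorted({r[0] for r in straight_rows} | {r[0] for r in circle_rows})
    subjects = pd.DataFrame({
        "subject_id": sids,
        "age_yr": 40, "mass_kg": 65.0, "height_m": 1.7,
        "leg_length_prosthesis_m": 0.95, "leg_length_intact_m": 0.95,
        "level": [levels[i % len(levels)] for i in range(len(sids))],
        "affected_side": "L", "sex": "M",
        "hours_on_legs_per_day": 5, "years_since_amputation": 10,
    })
    rows = [dict(subject_id=s, task="straight", trial_index=t, distance_m=D,
                 radius_m=np.nan, laps=np.nan, direction=np.nan, duration_s=T)
            for s, D, t, T in straight_rows]
    rows += [dict(subject_id=s, task="circle", trial_index=1, distance_m=np.nan,
                  radius_m=R, laps=laps, direction=d, duration_s=T)
             for s, R, laps, d, T in circle_rows]
    return CohortDataset(subjects=subjects, trials=pd.DataFrame(rows))


class TestConditionMeans:
    def test_straight_speed_is_distance_over_duration(self):
        cohort = tiny_cohort([("S1", 10.0, 1, 10.0), ("S2", 10.0, 1, 8.0)])
        means = gc.subject_condition_means(cohort)
        assert means.straight.loc["S1", 10.0] == pytest.approx(1.0)
        assert means.straight.loc["S2", 10.0] == pytest.approx(1.25)

    def test_circle_speed_is_lap_length_over_duration(self):
        cohort = tiny_cohort(
            [("S1", 23.0, 1, 20.0), ("S2", 23.0, 1, 20.0)],
            [("S1", 1.0, 5, "prosthesis_in", 10 * np.pi)],
        )
        means = gc.subject_condition_means(cohort)
        # 5 laps of 2*pi*1 m in 10*pi s -> 1 m/s
        assert means.circle.loc["S1", 1.0] == pytest.approx(1.0)

    def test_mean_over_repeat_trials(self):
        durations = [9.0, 10.0, 10.0, 11.0]
        cohort = tiny_cohort(
            [("S1", 10.0, t + 1, T) for t, T in enumerate(durations)]
            + [("S2", 10.0, 1, 10.0)]
        )
        means = gc.subject_condition_means(cohort)
        expected = np.mean([10.0 / T for T in durations])  # 1.005
        assert means.straight.loc["S1", 10.0] == pytest.approx(expected)
        assert expected == pytest.approx(1.005, abs=5e-4)

    def test_direction_kept_separate_and_pooled(self):
        cohort = tiny_cohort(
            [("S1", 23.0, 1, 20.0), ("S2", 23.0, 1, 20.0)],
            [("S1", 1.0, 5, "prosthesis_in", 10 * np.pi),
             ("S1", 1.0, 5, "prosthesis_out", 5 * np.pi)],
        )
        means = gc.subject_condition_means(cohort)
        by_dir = means.circle_by_direction.set_index("direction")["speed_m_s"]
        assert by_dir["prosthesis_in"] == pytest.approx(1.0)
        assert by_dir["prosthesis_out"] == pytest.approx(2.0)
        assert means.circle.loc["S1", 1.0] == pytest.approx(1.5)


class TestPercentReduction:
    def test_equal_speeds_give_zero(self):
        cohort = tiny_cohort([("S1", 23.0, 1, 23.0), ("S1", 4.0, 1, 4.0),
                              ("S2", 23.0, 1, 23.0), ("S2", 4.0, 1, 4.0)])
        out = gc.percent_reduction(cohort, "straight", 4.0)
        assert out.loc["all", "mean_pct"] == pytest.approx(0.0)
        assert out.loc["all", "sd_pct"] == pytest.approx(0.0)

    def test_ten_percent_slower_condition(self):
        # 4 m at 0.9 m/s vs 23 m at 1.0 m/s for every subject
        cohort = tiny_cohort([("S1", 23.0, 1, 23.0), ("S1", 4.0, 1, 4.0 / 0.9),
                              ("S2", 23.0, 1, 23.0), ("S2", 4.0, 1, 4.0 / 0.9)])
        out = gc.percent_reduction(cohort, "straight", 4.0)
        assert out.loc["all", "mean_pct"] == pytest.approx(10.0)
        assert out.loc["all", "sd_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_scale_free(self, noisy_cohort):
        out1 = gc.percent_reduction(noisy_cohort, "circle", 1.0)
        scaled = CohortDataset(
            subjects=noisy_cohort.subjects.copy(),
            trials=noisy_cohort.trials.assign(
                duration_s=lambda df: df["duration_s"] / 3.0
            ).drop(columns="speed_m_s"),
            provenance=noisy_cohort.provenance,
        )
        out2 = gc.percent_reduction(scaled, "circle", 1.0)
        pd.testing.assert_frame_equal(out1, out2)

    def test_subject_missing_baseline_excluded(self):
        cohort = tiny_cohort([("S1", 23.0, 1, 23.0), ("S1", 4.0, 1, 5.0),
                              ("S2", 4.0, 1, 5.0), ("S2", 10.0, 1, 10.0)])
        out = gc.percent_reduction(cohort, "straight", 4.0)
        assert out.loc["all", "n"] == 1


class TestBootstrapPaired:
    def test_all_positive_differences_floor_p(self):
        x = np.zeros(6)
        y = np.ones(6)
        res = gc.bootstrap_paired_onesided(x, y, n_boot=1000, seed=0)
        assert res.p_raw == pytest.approx(1e-3)
        assert res.p_floor_applied
        assert res.p_bonferroni == pytest.approx(1e-2)

    def test_all_zero_differences_give_p_one(self):
        x = np.ones(6)
        res = gc.bootstrap_paired_onesided(x, x, n_boot=1000, seed=0)
        assert res.p_raw == 1.0
        assert res.p_bonferroni == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = gc.bootstrap_paired_onesided(x, y, n_boot=5000, seed=42)
        b = gc.bootstrap_paired_onesided(x, y, n_boot=5000, seed=42)
        assert a == b

    def test_invariant_to_subject_order_and_common_shift(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=10), rng.normal(size=10)
        base = gc.bootstrap_paired_onesided(x, y, n_boot=2000, seed=3)
        perm = rng.permutation(10)
        reordered = gc.bootstrap_paired_onesided(x[perm], y[perm],
                                                 n_boot=2000, seed=3)
        shifted = gc.bootstrap_paired_onesided(x + 5.0, y + 5.0,
                                               n_boot=2000, seed=3)
        # differences are permuted, but the resampled distribution of the
        # mean difference is exchangeable: p must be equal for the same seed
        # under a common shift and close under reordering
        assert shifted.p_raw == base.p_raw
        assert abs(reordered.p_raw - base.p_raw) < 0.05

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(delta=st.floats(min_value=0.01, max_value=2.0))
    def test_monotone_in_effect_size(self, delta):
        rng = np.random.default_rng(11)
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.5, size=12)
        p0 = gc.bootstrap_paired_onesided(x, y, n_boot=2000, seed=9).p_raw
        p1 = gc.bootstrap_paired_onesided(x, y + delta, n_boot=2000,
                                          seed=9).p_raw
        assert p1 <= p0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            gc.bootstrap_paired_onesided([1.0], [2.0])

    def test_null_p_values_approximately_uniform(self):
        """Sign-flipped null: subject differences are symmetric around zero,
        so the bootstrap p-value should be close to uniform."""
        rng = np.random.default_rng(0)
        reps, n, n_boot = 2000, 12, 2000
        d = rng.standard_normal((reps, n))
        ps = np.empty(reps)
        for i in range(reps):
            idx = rng.integers(0, n, size=(n_boot, n))
            p = float(np.mean(d[i][idx].mean(axis=1) <= 0.0))
            ps[i] = max(p, 1.0 / n_boot)
        ks = np.max(np.abs(np.sort(ps) - np.arange(1, reps + 1) / reps))
        assert ks < 0.1


class TestPairedT:
    def test_constant_positive_differences_degenerate(self):
        res = gc.paired_t_onesided([0, 0, 0, 0], [1, 1, 1, 1])
        assert res.degenerate
        assert res.p_raw == 0.0

    def test_symmetric_differences_give_half(self):
        res = gc.paired_t_onesided([0.0, 0.0], [-1.0, 1.0])
        assert res.p_raw == pytest.approx(0.5)

    def test_hand_computed_t_statistic(self):
        # d = {0.1, 0.2, 0.3}: t = 0.2 / (0.1/sqrt(3)) = 2*sqrt(3)
        res = gc.paired_t_onesided([0.0, 0.0, 0.0], [0.1, 0.2, 0.3])
        expected_p = float(sps.t.sf(2.0 * np.sqrt(3.0), df=2))
        assert res.p_raw == pytest.approx(expected_p, rel=1e-9)
        assert expected_p == pytest.approx(0.03709, abs=5e-5)


class TestLinearFitSubjectOffsets:
    def test_noiseless_recovery_and_perfect_fit(self):
        rows = []
        offsets = {"S1": 0.9, "S2": 1.1, "S3": 1.0}
        for s, off in offsets.items():
            for D in (4.0, 6.0, 8.0, 10.0):
                rows.append({"subject_id": s, "distance_m": D,
                             "speed_m_s": 0.02 * D + off})
        fit = gc.linear_fit_subject_offsets(pd.DataFrame(rows), "distance_m")
        assert fit.slope == pytest.approx(0.02, abs=1e-12)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-10)
        for s, off in offsets.items():
            assert fit.subject_offsets[s] == pytest.approx(off, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        rows = []
        for i, s in enumerate(["S1", "S2", "S3"]):
            for D in (4.0, 6.0, 8.0, 10.0):
                rows.append({
                    "subject_id": s, "distance_m": D,
                    "speed_m_s": 0.015 * D + 0.9 + 0.1 * i
                    + rng.normal(scale=0.05),
                })
        df = pd.DataFrame(rows)
        fit = gc.linear_fit_subject_offsets(df, "distance_m")
        # direct least squares with subject indicator columns
        X = np.column_stack([
            df["distance_m"],
            (df["subject_id"] == "S1").astype(float),
            (df["subject_id"] == "S2").astype(float),
            (df["subject_id"] == "S3").astype(float),
        ])
        beta, *_ = np.linalg.lstsq(X, df["speed_m_s"], rcond=None)
        assert fit.slope == pytest.approx(beta[0], rel=1e-9)
        for j, s in enumerate(["S1", "S2", "S3"]):
            assert fit.subject_offsets[s] == pytest.approx(beta[1 + j], rel=1e-9)

    def test_single_record_subject_contributes_offset_only(self):
        rows = [{"subject_id": "S1", "distance_m": D,
                 "speed_m_s": 0.02 * D + 1.0} for D in (4.0, 6.0, 8.0)]
        rows.append({"subject_id": "S2", "distance_m": 6.0, "speed_m_s": 2.0})
        fit = gc.linear_fit_subject_offsets(pd.DataFrame(rows), "distance_m")
        assert fit.slope == pytest.approx(0.02, abs=1e-9)
        assert fit.subject_offsets["S2"] == pytest.approx(2.0 - 0.02 * 6.0)

    def test_single_predictor_value_rejected(self):
        rows = [{"subject_id": "S1", "distance_m": 4.0, "speed_m_s": 1.0},
                {"subject_id": "S2", "distance_m": 4.0, "speed_m_s": 1.1}]
        with pytest.raises(ValueError, match="distinct predictor"):
            gc.linear_fit_subject_offsets(pd.DataFrame(rows), "distance_m")

    def test_slope_bootstrap_detects_positive_slope(self):
        rows = []
        for i, s in enumerate(["S1", "S2", "S3", "S4"]):
            for D in (4.0, 6.0, 8.0, 10.0):
                rows.append({"subject_id": s, "distance_m": D,
                             "speed_m_s": 0.02 * D + 0.9 + 0.05 * i})
        res = _bootstrap_slope_positive(pd.DataFrame(rows), "distance_m",
                                        n_boot=1000, seed=0, name="slope")
        assert res.statistic == pytest.approx(0.02, abs=1e-9)
        assert res.p_floor_applied  # noiseless positive slope in every resample


class TestHypothesisBattery:
    def test_identical_speeds_everywhere_yield_no_evidence(self):
        cohort = gc.generate_cohort(gc.SyntheticConfig(
            constant_speed=1.0, sigma_subject=0.0, sigma_trial=0.0, seed=0
        ))
        battery = gc.run_hypothesis_battery(cohort, n_boot=500, seed=0)
        run = [t for t in battery if not t.skipped]
        assert len(run) == 11  # 10 pre-registered + post hoc
        assert all(t.p_bonferroni == 1.0 for t in run)

    def test_distance_and_radius_effects_detected_direction_not(
            self, noisy_cohort):
        battery = gc.run_hypothesis_battery(noisy_cohort, n_boot=5000, seed=0)
        by_name = {t.name: t for t in battery}
        # conditions with large generated effects (>=8% speed reduction or a
        # positive slope by construction) must come out significant
        strong = [
            "speed(23 m) > speed(4 m)",
            "speed(23 m) > speed(6 m)",
            "speed(23 m) > speed(8 m)",
            "speed(23 m) > speed(10 m)",
            "speed-distance slope > 0 (short bouts)",
            "speed(23 m straight) > speed(R=1 m)",
            "speed(23 m straight) > speed(R=2 m)",
            "speed-radius slope > 0 (circles)",
        ]
        for name in strong:
            assert by_name[name].p_bonferroni < 0.05, name
        direction = by_name["speed(prosthesis out) > speed(prosthesis in)"]
        assert direction.p_bonferroni > 0.05

    def test_battery_is_deterministic_given_seed(self, noisy_cohort):
        a = gc.run_hypothesis_battery(noisy_cohort, n_boot=500, seed=7)
        b = gc.run_hypothesis_battery(noisy_cohort, n_boot=500, seed=7)
        assert [t.to_record() for t in a] == [t.to_record() for t in b]

    def test_missing_condition_produces_skip_record(self, noisy_cohort):
        trimmed = CohortDataset(
            subjects=noisy_cohort.subjects.copy(),
            trials=noisy_cohort.trials[
                noisy_cohort.trials["distance_m"] != 6.0
            ].copy(),
            provenance=noisy_cohort.provenance,
        )
        battery = gc.run_hypothesis_battery(trimmed, n_boot=200, seed=0)
        skipped = [t for t in battery if t.skipped]
        assert len(skipped) == 1
        assert "6" in skipped[0].name

    def test_trial_level_resampling_switch(self, noisy_cohort):
        battery = gc.run_hypothesis_battery(noisy_cohort, n_boot=500, seed=0,
                                            resample_unit="trials")
        methods = {t.method for t in battery if not t.skipped}
        assert "bootstrap(trials)" in methods

    def test_direction_effect_recovered_in_post_hoc_test(self):
        cohort = gc.generate_cohort(gc.SyntheticConfig(
            sigma_subject=0.0, sigma_trial=0.0, direction_effect=0.05, seed=0
        ))
        battery = gc.run_hypothesis_battery(cohort, n_boot=2000, seed=0)
        post_hoc = [t for t in battery if t.post_hoc][0]
        assert post_hoc.statistic == pytest.approx(0.05, abs=1e-9)
        assert post_hoc.p_raw <= 1e-3
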