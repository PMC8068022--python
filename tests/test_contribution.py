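import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

import gripsig as gs
from gripsig.contribution_analysis import CGFMatrix, mean_cgf, _pearson_matrix
from gripsig.preprocessing import NormalizedCurve, TAU_GRID


def _curve(values):
    return NormalizedCurve(np.asarray(values, dtype=float))


def _const_curves(levels):
    return {f"S{i + 1:02d}": _curve(np.full(101, v)) for i, v in enumerate(levels)}


class TestScaleToReference:
    def test_factor_is_mean_ratio(self):
        gf = {"S01": _curve(np.full(101, 40.0)), "S02": _curve(np.full(101, 20.0))}
        region = {s: np.tile(c.values[:, None] / 18, (1, 18)) for s, c in gf.items()}
        sgf, sregion, factors = gs.scale_to_reference(gf, region, "S01")
        assert factors["S02"] == pytest.approx(2.0)
        assert sgf["S02"].values.mean() == pytest.approx(40.0)

    def test_reference_unchanged(self):
        gf = {"S01": _curve(np.full(101, 40.0)), "S02": _curve(np.full(101, 20.0))}
        region = {s: np.zeros((101, 18)) for s in gf}
        sgf, _, factors = gs.scale_to_reference(gf, region, "S01")
        assert factors["S01"] == 1.0
        np.testing.assert_array_equal(sgf["S01"].values, gf["S01"].values)

    def test_scaling_leaves_cgf_invariant(self):
        rng = np.random.default_rng(0)
        gf_vals = 1.0 + rng.uniform(0, 5, 101)
        shares = rng.dirichlet(np.ones(18))
        region = gf_vals[:, None] * shares[None, :]
        before = mean_cgf(gf_vals, region)
        after = mean_cgf(3.7 * gf_vals, 3.7 * region)
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            gs.scale_to_reference(_const_curves([1.0]), {"S01": np.zeros((101, 18))}, "SX")


class TestDiscardOutliers:
    def test_constructed_outliers_discarded(self):
        rng = np.random.default_rng(1)
        base = np.sin(np.pi * TAU_GRID) * 10
        curves = {f"S{i + 1:02d}": _curve(base + rng.normal(0, 0.01, 101)) for i in range(18)}
        outliers = ["S19", "S20", "S21", "S22"]
        for j, s in enumerate(outliers):
            curves[s] = _curve(base + (5.0 + j) * np.cos(np.pi * TAU_GRID))
        retained = gs.discard_outliers(curves, n_discard=4)
        assert len(retained) == 18
        assert set(retained) & set(outliers) == set()

    def test_zero_discard_retains_all(self):
        curves = _const_curves([1, 2, 3])
        assert gs.discard_outliers(curves, n_discard=0) == sorted(curves)

    def test_22_subjects_default_retains_18(self):
        rng = np.random.default_rng(2)
        curves = {f"S{i + 1:02d}": _curve(rng.uniform(0, 1, 101)) for i in range(22)}
        assert len(gs.discard_outliers(curves)) == 18

    def test_too_many_discards_rejected(self):
        with pytest.raises(ValueError):
            gs.discard_outliers(_const_curves([1, 2]), n_discard=2)


class TestMeanTaskCurve:
    def test_two_constant_curves(self):
        curves = _const_curves([10.0, 20.0])
        mean, sd = gs.mean_task_curve(curves)
        np.testing.assert_allclose(mean.values, 15.0)
        np.testing.assert_allclose(sd.values, np.sqrt(50.0))  # sample SD ~ 7.07

    def test_identical_curves_zero_sd(self):
        curves = _const_curves([5.0, 5.0, 5.0])
        _, sd = gs.mean_task_curve(curves)
        np.testing.assert_allclose(sd.values, 0.0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            gs.mean_task_curve(_const_curves([1.0]))


class TestMeanCGF:
    def test_constant_shares_recovered_exactly(self):
        rng = np.random.default_rng(3)
        shares = rng.dirichlet(np.ones(18))
        gf = gs.bump_profile([(0.5, 0.8, 20.0)])(TAU_GRID)
        region = gf[:, None] * shares[None, :]
        np.testing.assert_allclose(mean_cgf(gf, region), shares, atol=1e-12)

    def test_all_force_in_region_18(self):
        gf = gs.bump_profile([(0.5, 0.8, 20.0)])(TAU_GRID)
        region = np.zeros((101, 18))
        region[:, 17] = gf
        out = mean_cgf(gf, region)
        expected = np.zeros(18)
        expected[17] = 1.0
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_two_phase_window_selects_high_gf_share(self):
        # GF: 60 frames at 2 N (low), 41 frames at 10 N (high); mean ~ 5.25 N
        # -> window is exactly the high phase, whose share differs
        gf = np.where(np.arange(101) < 60, 2.0, 10.0)
        region = np.zeros((101, 18))
        region[:60, 0] = gf[:60]  # low phase: all in region 1
        region[60:, 1] = gf[60:]  # high phase: all in region 2
        out = mean_cgf(gf, region)
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(1.0)

    def test_constant_gf_falls_back_to_positive_window(self):
        gf = np.full(101, 5.0)
        region = np.zeros((101, 18))
        region[:, 4] = 5.0
        out = mean_cgf(gf, region)
        assert out[4] == pytest.approx(1.0)

    def test_zero_gf_rejected(self):
        with pytest.raises(ValueError):
            mean_cgf(np.zeros(101), np.zeros((101, 18)))

    @settings(max_examples=20, deadline=None)
    @given(st_.integers(0, 2**32 - 1))
    def test_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        gf = rng.uniform(0.5, 30.0, 101)
        shares = rng.dirichlet(np.ones(18), size=101)
        region = gf[:, None] * shares
        assert mean_cgf(gf, region).sum() == pytest.approx(1.0, abs=1e-9)


def _cgf_matrix(cube, tasks=None):
    S, K, _ = cube.shape
    subjects = [f"S{i + 1:02d}" for i in range(S)]
    tasks = tasks or list(range(1, K + 1))
    return CGFMatrix(subjects=subjects, tasks=tasks, mean_cgf=cube,
                     retained_subjects={t: subjects for t in tasks})


class TestCorrelations:
    def test_identical_task_patterns_r_one(self):
        rng = np.random.default_rng(4)
        pat = rng.dirichlet(np.ones(18))
        cube = np.tile(pat, (3, 2, 1))
        tc = gs.task_correlations(_cgf_matrix(cube))
        assert tc[0, 1] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(18))
        y = 0.01 + 0.8 * x
        y = y / y.sum()  # still affine in x
        cube = np.stack([np.stack([x, y])])  # 1 subject, 2 tasks
        tc = gs.task_correlations(_cgf_matrix(cube))
        assert tc[0, 1] == pytest.approx(1.0)

    def test_three_tasks_match_brute_force(self):
        rng = np.random.default_rng(6)
        cube = rng.dirichlet(np.ones(18), size=(4, 3))
        m = _cgf_matrix(cube)
        tc = gs.task_correlations(m)
        patterns = m.task_region_mean
        for a in range(3):
            for b in range(3):
                x, y = patterns[a], patterns[b]
                expected = np.corrcoef(x, y)[0, 1]
                assert tc[a, b] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(tc, tc.T)
        np.testing.assert_allclose(np.diag(tc), 1.0)

    def test_complementary_regions_r_minus_one(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.2, 0.8, size=(5, 4))
        cube = np.zeros((5, 4, 18))
        cube[:, :, 0] = x
        cube[:, :, 1] = 1.0 - x
        rc = gs.region_correlations(_cgf_matrix(cube))
        assert rc[0, 1] == pytest.approx(-1.0)

    def test_duplicated_region_columns_r_one(self):
        rng = np.random.default_rng(8)
        cube = np.zeros((5, 3, 18))
        v = rng.uniform(0, 0.5, size=(5, 3))
        cube[:, :, 2] = v
        cube[:, :, 3] = v
        rc = gs.region_correlations(_cgf_matrix(cube))
        assert rc[2, 3] == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        cube = np.zeros((3, 2, 18))
        cube[:, :, 0] = 0.5  # constant -> zero variance
        cube[:, :, 1] = np.random.default_rng(9).uniform(0, 1, (3, 2))
        rc = gs.region_correlations(_cgf_matrix(cube))
        assert np.isnan(rc[0, 1])

    def test_entries_bounded(self):
        rng = np.random.default_rng(10)
        cube = rng.dirichlet(np.ones(18), size=(6, 4))
        rc = gs.region_correlations(_cgf_matrix(cube))
        finite = rc[np.isfinite(rc)]
        assert np.all(finite <= 1 + 1e-12) and np.all(finite >= -1 - 1e-12)


class TestPeakTable:
    def test_single_subject_single_task(self):
        rng = np.random.default_rng(11)
        f = rng.uniform(0, 10, 18)
        p = rng.uniform(0, 300, 18)
        table = gs.peak_table({("S01", 1): f}, {("S01", 1): p}, {1: ["S01"]}, [1])
        np.testing.assert_allclose(table.peak_force_n, f)
        np.testing.assert_allclose(table.peak_pressure_kpa, p)
        assert np.all(table.peak_force_task == 1)

    def test_dominant_task_wins_everywhere(self):
        rng = np.random.default_rng(12)
        f = rng.uniform(1, 10, 18)
        peaks_f = {("S01", 1): f, ("S01", 2): 2 * f}
        peaks_p = {("S01", 1): f * 10, ("S01", 2): 20 * f}
        table = gs.peak_table(peaks_f, peaks_p, {1: ["S01"], 2: ["S01"]}, [1, 2])
        assert np.all(table.peak_force_task == 2)
        assert np.all(table.peak_pressure_task == 2)

    def test_two_by_two_hand_computed(self):
        fa = np.zeros(18); fa[0] = 4.0
        fb = np.zeros(18); fb[0] = 6.0
        fc = np.zeros(18); fc[0] = 3.0
        fd = np.zeros(18); fd[0] = 5.0
        peaks_f = {("S01", 1): fa, ("S02", 1): fb, ("S01", 2): fc, ("S02", 2): fd}
        peaks_p = {k: v * 10 for k, v in peaks_f.items()}
        table = gs.peak_table(peaks_f, peaks_p,
                              {1: ["S01", "S02"], 2: ["S01", "S02"]}, [1, 2])
        # task 1 average 5.0, task 2 average 4.0 -> max 5.0 in task 1
        assert table.peak_force_n[0] == pytest.approx(5.0)
        assert table.peak_force_task[0] == 1


class TestDurations:
    def test_median(self):
        stats = gs.task_duration_stats({1: [10.0, 12.0, 14.0]})
        assert stats[1]["median"] == pytest.approx(12.0)

    def test_equal_durations_no_outliers(self):
        stats = gs.task_duration_stats({1: [7.0] * 6})
        assert stats[1]["n_outliers"] == 0
        assert stats[1]["q3"] - stats[1]["q1"] == 0.0

    def test_extreme_value_flagged(self):
        vals = [10.0, 10.5, 11.0, 11.5, 12.0, 30.0]
        stats = gs.task_duration_stats({1: vals})
        assert stats[1]["n_outliers"] == 1
        assert stats[1]["outliers"] == [30.0]
        # direct 1.5*IQR rule evaluation
        q1, q3 = np.percentile(vals, [25, 75])
        assert 30.0 > q3 + 1.5 * (q3 - q1)
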