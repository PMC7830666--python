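import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import multichaos as mc
from multichaos.embedding import EmbeddingParams
from multichaos.glle import (DivergenceCurve, GLLEEstimate, GLLESpectrum,
                             divergence_curve, fit_glle, mean_period,
                             nearest_neighbor_indices, pnorm_distance)


class TestPnormDistance:
    @pytest.mark.parametrize("p,expected", [
        (2, 5.0),
        (1, 7.0),
        (0.5, (np.sqrt(3) + 2) ** 2),
    ])
    def test_three_four_triangle(self, p, expected):
        assert pnorm_distance((3, 4), (0, 0), p) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(mc.ParameterError):
            pnorm_distance((1, 2, 3), (1, 2), 2)

    def test_near_zero_p_rejected(self):
        with pytest.raises(mc.ParameterError):
            pnorm_distance((1, 2), (0, 0), 0.01)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_non_increasing_in_p(self, coords):
        """Classical l_p monotonicity: ||x||_p shrinks as p grows."""
        u = np.asarray(coords)
        v = np.zeros_like(u)
        ds = [pnorm_distance(u, v, p) for p in (0.25, 0.5, 1, 2, 4, 8)]
        assert all(a >= b - 1e-9 * max(1.0, abs(a)) for a, b in zip(ds, ds[1:]))


def _toy_trajectory(n=50, m=3, seed=0):
    rng = np.random.default_rng(seed)
    ts = mc.TimeSeries(rng.normal(size=n + (m - 1)))
    return mc.embed(ts, EmbeddingParams(m=m, J=1))


class TestNearestNeighbors:
    def test_collinear_points(self):
        ts = mc.TimeSeries(np.array([0.0, 1.0, 3.0]))
        traj = mc.embed(ts, EmbeddingParams(m=1, J=1))
        nn = nearest_neighbor_indices(traj, p=2, min_sep=0)
        np.testing.assert_array_equal(nn, [1, 0, 1])

    @pytest.mark.parametrize("p", [0.5, 1, 2, 5])
    @pytest.mark.parametrize("min_sep", [0, 3])
    def test_matches_brute_force(self, p, min_sep):
        traj = _toy_trajectory()
        nn = nearest_neighbor_indices(traj, p=p, min_sep=min_sep)
        X = traj.rows
        for j in range(len(X)):
            d = np.sum(np.abs(X - X[j]) ** p, axis=1)
            d[np.abs(np.arange(len(X)) - j) <= min_sep] = np.inf
            assert nn[j] == int(np.argmin(d))

    def test_min_sep_excluding_everything_flags_all_rows(self):
        traj = _toy_trajectory(n=20, m=2)
        nn = nearest_neighbor_indices(traj, p=2, min_sep=len(traj))
        assert np.all(nn == -1)
        with pytest.raises(mc.DegenerateSeriesError):
            divergence_curve(traj, nn, p=2, k_max=5)


class TestDivergenceCurve:
    def test_matches_hand_brute_force(self):
        traj = _toy_trajectory(n=10, m=2, seed=3)
        nn = nearest_neighbor_indices(traj, p=2, min_sep=0)
        curve = divergence_curve(traj, nn, p=2, k_max=4)
        X = traj.rows
        M = len(X)
        for i in range(5):
            logs = []
            for j in range(M):
                jn = nn[j]
                if j + i < M and jn + i < M:
                    d = np.sqrt(np.sum((X[j + i] - X[jn + i]) ** 2))
                    if d > 0:
                        logs.append(np.log(d))
            assert curve.values[i] == pytest.approx(np.mean(logs))
            assert curve.n_valid[i] == len(logs)

    def test_step_zero_is_mean_log_initial_separation(self):
        traj = _toy_trajectory(n=40, m=2, seed=4)
        nn = nearest_neighbor_indices(traj, p=1, min_sep=1)
        curve = divergence_curve(traj, nn, p=1, k_max=3, dt=0.5)
        d0 = [pnorm_distance(traj.rows[j], traj.rows[nn[j]], 1)
              for j in range(len(traj))]
        assert curve.values[0] == pytest.approx(np.mean(np.log(d0)) / 0.5)

    def test_duplicate_rows_excluded_not_minus_inf(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.5, 2.0, 3.0, 5.0])
        traj = mc.embed(mc.TimeSeries(x), EmbeddingParams(m=2, J=1))
        nn = nearest_neighbor_indices(traj, p=2, min_sep=0)
        curve = divergence_curve(traj, nn, p=2, k_max=2)
        assert np.all(np.isfinite(curve.values[curve.n_valid > 0]))

    def test_valid_pair_count_never_increases(self, logistic_series):
        traj = mc.embed(logistic_series.truncate(800), EmbeddingParams(m=2, J=1))
        nn = nearest_neighbor_indices(traj, p=2, min_sep=2)
        curve = divergence_curve(traj, nn, p=2, k_max=50)
        assert np.all(np.diff(curve.n_valid) <= 0)


class TestFitGlle:
    def test_exact_line_recovered_to_machine_precision(self):
        steps = np.arange(101)
        curve = DivergenceCurve(steps=steps, values=0.7 * steps - 3.0,
                                n_valid=np.full(101, 10), dt=1.0, p=2)
        est = fit_glle(curve, window=(0, 40))
        assert est.glle == pytest.approx(0.7, abs=1e-12)
        assert est.fit_r2 == pytest.approx(1.0)

    def test_constant_curve_gives_zero_slope(self):
        steps = np.arange(51)
        curve = DivergenceCurve(steps=steps, values=np.full(51, 2.0),
                                n_valid=np.full(51, 5), dt=1.0, p=1)
        assert fit_glle(curve).glle == pytest.approx(0.0)

    def test_too_few_valid_points_raises(self):
        steps = np.arange(20)
        vals = np.full(20, np.nan)
        vals[:2] = [0.0, 1.0]
        curve = DivergenceCurve(steps=steps, values=vals,
                                n_valid=(~np.isnan(vals)).astype(int),
                                dt=1.0, p=2)
        with pytest.raises(mc.ParameterError):
            fit_glle(curve, window=(0, 19))

    def test_scaling_band_ignores_saturated_tail(self):
        # kinked curve: slope 1 for 20 steps, then flat
        steps = np.arange(101)
        vals = np.minimum(steps.astype(float), 20.0)
        curve = DivergenceCurve(steps=steps, values=vals,
                                n_valid=np.full(101, 8), dt=1.0, p=2)
        est = fit_glle(curve)
        assert est.glle == pytest.approx(1.0, abs=0.05)


def _euclidean_rosenstein(x, m, J, min_sep, k_max, window):
    """Independent plain-Euclidean Rosenstein estimator (oracle).

    Deliberately naive: explicit loops, no shared code with the package.
    """
    N = len(x)
    M = N - (m - 1) * J
    X = np.array([[x[i + k * J] for k in range(m)] for i in range(M)])
    nn = []
    for j in range(M):
        best, best_d = -1, np.inf
        for jj in range(M):
            if abs(j - jj) <= min_sep:
                continue
            d = np.sqrt(np.sum((X[j] - X[jj]) ** 2))
            if d < best_d:
                best, best_d = jj, d
        nn.append(best)
    ys = []
    for i in range(k_max + 1):
        logs = [np.log(np.sqrt(np.sum((X[j + i] - X[nn[j] + i]) ** 2)))
                for j in range(M)
                if j + i < M and nn[j] + i < M
                and np.sum((X[j + i] - X[nn[j] + i]) ** 2) > 0]
        ys.append(np.mean(logs))
    lo, hi = window
    t = np.arange(lo, hi + 1, dtype=float)
    y = np.array(ys[lo:hi + 1])
    slope = np.polyfit(t, y, 1)[0]
    return np.array(ys), slope


class TestEuclideanEquivalence:
    def test_p2_pipeline_equals_dedicated_rosenstein(self):
        """The p-norm generalization collapses to classical Rosenstein at p=2."""
        x = mc.simulate("henon", n_samples=300, seed=9).values
        m, J, min_sep, k_max, window = 2, 1, 2, 30, (0, 10)
        ys_oracle, slope_oracle = _euclidean_rosenstein(x, m, J, min_sep,
                                                        k_max, window)
        ts = mc.TimeSeries(x)
        traj = mc.embed(ts, EmbeddingParams(m=m, J=J))
        nn = nearest_neighbor_indices(traj, p=2, min_sep=min_sep)
        curve = divergence_curve(traj, nn, p=2, k_max=k_max)
        np.testing.assert_allclose(curve.values, ys_oracle, rtol=1e-10)
        est = fit_glle(curve, window=window)
        assert est.glle == pytest.approx(slope_oracle, rel=1e-9)


class TestSpectrum:
    def test_single_p_spectrum_has_zero_width(self, logistic_series):
        spec = mc.glle_spectrum(logistic_series.truncate(1500),
                                EmbeddingParams(m=2, J=1), p_grid=[2])
        assert spec.width == 0.0

    def test_two_entry_width(self):
        spec = GLLESpectrum(estimates=(
            GLLEEstimate(p=1, glle=0.2, fit_window=(0, 5), fit_r2=1.0),
            GLLEEstimate(p=2, glle=0.5, fit_window=(0, 5), fit_r2=1.0)))
        assert mc.spectrum_width(spec) == pytest.approx(0.3)

    def test_width_nonnegative_over_random_subseries(self, henon_series):
        rng = np.random.default_rng(0)
        for _ in range(3):
            start = int(rng.integers(0, 2000))
            ts = mc.TimeSeries(henon_series.values[start:start + 1200])
            spec = mc.glle_spectrum(ts, EmbeddingParams(m=2, J=1),
                                    p_grid=[0.5, 2, 5])
            assert spec.width >= 0.0

    def test_unsorted_grid_rejected(self, logistic_series):
        with pytest.raises(mc.ParameterError):
            mc.glle_spectrum(logistic_series, EmbeddingParams(m=2, J=1),
                             p_grid=[2, 1])

    def test_logistic_recovers_ln2(self, logistic_series):
        """Parameter recovery: GLLE(2) of the mu=4 logistic map is ln 2."""
        spec = mc.glle_spectrum(logistic_series, EmbeddingParams(m=2, J=1),
                                p_grid=[2])
        assert spec[2].glle == pytest.approx(np.log(2), abs=0.05)


class TestMeanPeriod:
    def test_sine_period_recovered(self, sine_series):
        assert mean_period(sine_series) == pytest.approx(40.0, rel=0.05)

    def test_constant_series_raises(self):
        with pytest.raises(mc.DegenerateSeriesError):
            mean_period(mc.TimeSeries(np.ones(64)))
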