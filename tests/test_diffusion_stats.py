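"""TAMSD, curve collapse, generalized Gaussian fits and non-Gaussianity."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hrtb import diffusion_stats as ds
from hrtb.trajectories import Ensemble, Track

from conftest import make_track_1d, make_track_3d


def brute_force_tamsd(track, lag, p):
    dt = track.frame_dt()
    k = int(round(lag / dt))
    vals = []
    for i in range(track.n_frames - k):
        vals.append(np.linalg.norm(track.positions[i + k] - track.positions[i]) ** p)
    return float(np.mean(vals))


class TestTamsdMoment:
    def test_enumerated_windows(self):
        track = make_track_1d([0, 1, 1, 3])
        assert ds.tamsd_moment(track, 3.0, p=2) == pytest.approx(5 / 3)

    @pytest.mark.parametrize("lag", [3.0, 9.0, 27.0])
    def test_ballistic_closed_form(self, lag):
        v = 1.7
        track = make_track_1d(v * np.arange(0, 60, 3), dt=3.0)
        assert ds.tamsd_moment(track, lag, 2) == pytest.approx((v * lag) ** 2)
        assert ds.tamsd_moment(track, lag, 4) == pytest.approx((v * lag) ** 4)

    def test_stationary_track_is_zero(self):
        track = make_track_1d([5.0] * 10)
        assert ds.tamsd_moment(track, 6.0, 2) == 0.0
        assert ds.tamsd_moment(track, 6.0, 4) == 0.0

    def test_invalid_lag_and_order_rejected(self):
        track = make_track_1d([0, 1, 2, 3])
        with pytest.raises(ValueError):
            ds.tamsd_moment(track, 9.0, 2)  # lag == duration
        with pytest.raises(ValueError):
            ds.tamsd_moment(track, 4.0, 2)  # off the frame grid
        with pytest.raises(ValueError):
            ds.tamsd_moment(track, 3.0, 3)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=1, max_value=9))
    def test_matches_brute_force_double_loop(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(k + 2, 30))
        pos = np.cumsum(rng.normal(size=(n, 3)), axis=0)
        track = make_track_3d(pos)
        for p in (2, 4):
            assert ds.tamsd_moment(track, 3.0 * k, p) == pytest.approx(
                brute_force_tamsd(track, 3.0 * k, p))


class TestEnsembleAverage:
    def _curve(self, lags, values):
        lags = np.asarray(lags, float)
        return ds.LagCurve(lags, np.asarray(values, float),
                           np.ones(lags.size, int))

    def test_identical_curves_unchanged(self):
        c = self._curve([3, 6], [1.0, 2.0])
        avg = ds.ensemble_average([c, c, c])
        np.testing.assert_allclose(avg.values, c.values)
        assert avg.n_contributing.tolist() == [3, 3]

    def test_arithmetic_mean(self):
        avg = ds.ensemble_average(
            [self._curve([3], [1.0]), self._curve([3], [3.0])])
        assert avg.values[0] == pytest.approx(2.0)

    def test_disjoint_grids_rejected(self):
        with pytest.raises(ValueError, match="intersection"):
            ds.ensemble_average(
                [self._curve([3], [1.0]), self._curve([6], [1.0])])


class TestFitPowerLaw:
    @pytest.mark.parametrize("a", [0.5, 1.0, 1.5, 2.0])
    @pytest.mark.parametrize("c", [0.3, 7.0])
    def test_exact_power_law_recovered(self, a, c):
        lags = np.arange(3.0, 60.1, 3.0)
        curve = ds.LagCurve(lags, c * lags**a, np.ones(lags.size, int))
        fit = ds.fit_power_law(curve, (3, 60))
        assert fit.alpha == pytest.approx(a, abs=1e-10)
        assert fit.log_intercept == pytest.approx(np.log(c), abs=1e-9)

    def test_nonpositive_values_rejected(self):
        lags = np.array([3.0, 6.0, 9.0, 12.0])
        curve = ds.LagCurve(lags, np.array([1.0, 0.0, 1.0, 1.0]),
                            np.ones(4, int))
        with pytest.raises(ValueError):
            ds.fit_power_law(curve, (3, 12))

    def test_brownian_ensemble_is_fickian(self, brownian_ensemble):
        lags = np.arange(3.0, 60.1, 3.0)
        avg = ds.ensemble_average(
            [ds.tamsd_curve(t, lags) for t in brownian_ensemble])
        fit = ds.fit_power_law(avg, (3, 60))
        assert fit.alpha == pytest.approx(1.0, abs=0.05)


class TestLaggedDisplacements:
    def test_enumeration(self):
        ens = Ensemble(tracks=(make_track_1d([0, 1, 1, 3]),))
        np.testing.assert_allclose(
            ds.lagged_displacements(ens, "x", 3.0), [1, 0, 2])

    def test_ballistic_constant(self):
        v = 2.0
        ens = Ensemble(tracks=(make_track_1d(v * np.arange(0, 30, 3)),))
        samples = ds.lagged_displacements(ens, "x", 6.0)
        np.testing.assert_allclose(samples, v * 6.0)

    def test_excessive_lag_rejected(self):
        ens = Ensemble(tracks=(make_track_1d([0, 1, 2]),))
        with pytest.raises(ValueError):
            ds.lagged_displacements(ens, "x", 60.0)

    def test_min_duration_restricts_track_set(self):
        ens = Ensemble(tracks=(make_track_1d([0, 1, 2], track_id="short"),
                               make_track_1d(np.arange(50), track_id="long")))
        short_included = ds.lagged_displacements(ens, "x", 3.0)
        only_long = ds.lagged_displacements(ens, "x", 3.0, min_duration=120.0)
        assert short_included.size == only_long.size + 2


class TestWasserstein:
    def test_identical_zero(self):
        assert ds.wasserstein_1d([1.0, 2.0], [2.0, 1.0]) == 0.0

    def test_shifted_point_masses(self):
        assert ds.wasserstein_1d([0.0], [1.0]) == pytest.approx(1.0)

    def test_piecewise_cdf_integration(self):
        assert ds.wasserstein_1d([0.0, 1.0], [0.0, 2.0]) == pytest.approx(0.5)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        u, v, w = (rng.normal(size=rng.integers(1, 8)) for _ in range(3))
        duv = ds.wasserstein_1d(u, v)
        assert duv >= 0
        assert duv == pytest.approx(ds.wasserstein_1d(v, u))
        assert ds.wasserstein_1d(u, u) == 0.0
        assert duv <= (ds.wasserstein_1d(u, w) + ds.wasserstein_1d(w, v)
                       + 1e-12)


class TestOptimizeCollapse:
    def test_ballistic_mixed_speeds_collapse_at_one(self):
        from hrtb.synthetic import gen_ballistic

        rng = np.random.default_rng(3)
        ens, _ = gen_ballistic(20, 60, speeds=rng.uniform(0.5, 2.0, 20),
                               seed=3)
        res = ds.optimize_collapse(
            ens, lags=(3, 6, 15, 30, 60),
            beta_grid=np.round(np.arange(0.3, 1.201, 0.01), 3))
        assert res.beta == pytest.approx(1.0, abs=0.05)

    def test_singleton_grid_returned(self, brownian_ensemble):
        res = ds.optimize_collapse(brownian_ensemble, lags=(3, 6),
                                   beta_grid=[0.77])
        assert res.beta == 0.77

    def test_criterion_minimum_is_at_reported_beta(self, brownian_ensemble):
        res = ds.optimize_collapse(
            brownian_ensemble, lags=(3, 6, 15, 30),
            beta_grid=np.round(np.arange(0.35, 0.81, 0.05), 2))
        i = np.argmin(res.criterion)
        assert res.beta_grid[i] == res.beta
        assert np.all(res.criterion >= res.criterion[i])


class TestGeneralizedGaussian:
    def test_normal_samples_give_gamma_two(self):
        x = np.random.default_rng(11).normal(size=100_000)
        fit = ds.fit_generalized_gaussian(x)
        assert fit.gamma == pytest.approx(2.0, abs=0.1)
        assert fit.sigma == pytest.approx(np.sqrt(2.0), abs=0.05)

    def test_laplace_samples_give_gamma_one(self):
        x = np.random.default_rng(12).laplace(size=100_000)
        fit = ds.fit_generalized_gaussian(x)
        assert fit.gamma == pytest.approx(1.0, abs=0.1)

    def test_scale_equivariance(self):
        x = np.random.default_rng(13).normal(size=5_000)
        base = ds.fit_generalized_gaussian(x)
        scaled = ds.fit_generalized_gaussian(3.5 * x)
        assert scaled.gamma == pytest.approx(base.gamma, rel=1e-6)
        assert scaled.sigma == pytest.approx(3.5 * base.sigma, rel=1e-6)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            ds.fit_generalized_gaussian(np.ones(100))

    def test_agrees_with_independent_mle(self):
        x = np.random.default_rng(14).laplace(size=20_000)
        ours = ds.fit_generalized_gaussian(x)
        beta, loc, scale = sps.gennorm.fit(x, floc=0.0)
        assert ours.gamma == pytest.approx(beta, abs=0.02)
        assert ours.sigma == pytest.approx(scale, rel=0.02)


class TestNonGaussianity:
    def test_laplace_increments_closed_form(self):
        rng = np.random.default_rng(21)
        x = np.cumsum(rng.laplace(size=20_000))
        ens = Ensemble(tracks=(make_track_1d(x),))
        g = ds.non_gaussianity(ens, [3.0], d=1)
        # Laplace: <x^4>/<x^2>^2 = 6, so G = 6/3 - 1 = 1
        assert g.values[0] == pytest.approx(1.0, abs=0.15)

    def test_fixed_magnitude_steps_closed_form(self):
        rng = np.random.default_rng(22)
        x = np.cumsum(rng.choice([-1.0, 1.0], size=5_000))
        ens = Ensemble(tracks=(make_track_1d(x),))
        g = ds.non_gaussianity(ens, [3.0], d=1)
        assert g.values[0] == pytest.approx(-2 / 3, abs=1e-9)

    def test_invariant_under_global_rotation(self, brownian_ensemble):
        from scipy.spatial.transform import Rotation

        lags = [3.0, 15.0]
        g0 = ds.non_gaussianity(brownian_ensemble, lags, d=3)
        rot = Rotation.from_euler("zyx", [40, 25, 10], degrees=True).as_matrix()
        rotated = Ensemble(
            tracks=tuple(
                Track(t.track_id, t.times, t.positions @ rot.T)
                for t in brownian_ensemble
            ),
            nominal_dt=brownian_ensemble.nominal_dt,
        )
        g1 = ds.non_gaussianity(rotated, lags, d=3)
        np.testing.assert_allclose(g1.values, g0.values, atol=1e-10)


class TestSplitByPersistence:
    def _decomp(self, tid, angle):
        from hrtb.coarse_grain import RunDecomposition

        return RunDecomposition(tid, np.array([8.0, 8.0]),
                                np.array([6.0, 6.0]), np.array([angle]))

    def test_all_below_threshold(self):
        pers, rest = ds.split_by_persistence(
            [self._decomp("a", 0.5), self._decomp("b", 1.0)], 1.5)
        assert pers == ["a", "b"] and rest == []

    def test_mixed_groups(self):
        pers, rest = ds.split_by_persistence(
            [self._decomp("a", 1.0), self._decomp("b", 1.6)], 1.5)
        assert (pers, rest) == (["a"], ["b"])

    def test_boundary_goes_to_less_persistent(self):
        pers, rest = ds.split_by_persistence([self._decomp("a", 1.5)], 1.5)
        assert (pers, rest) == ([], ["a"])
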