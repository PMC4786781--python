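"""Langmuir fits, rate-constant regression, Hill isotherm, compaction."""

import numpy as np
import pytest

from pifeflow.containers import Trajectory
from pifeflow.kinetics import (
    PhotobleachModel,
    correct_photobleaching,
    estimate_lag_and_rate,
    estimate_rate_constants,
    fit_association,
    fit_dissociation,
    fit_hill,
    normalize_fold,
)


def _traj(values, dt=0.1, kind="fold"):
    values = np.asarray(values, float)
    return Trajectory(time_s=np.arange(values.size) * dt, values=values,
                      kind=kind)


class TestNormalizeFold:
    def test_constant_maps_to_one(self):
        fold = normalize_fold(_traj(np.full(100, 37.0), kind="intensity"), 20)
        np.testing.assert_allclose(fold.values, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        y = 1000 + rng.normal(0, 10, 200).cumsum()
        a = normalize_fold(_traj(y, kind="intensity"), 20).values
        b = normalize_fold(_traj(2 * y, kind="intensity"), 20).values
        np.testing.assert_allclose(a, b)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_fold(_traj(np.zeros(50), kind="intensity"), 20)


class TestPhotobleachCorrection:
    def test_factor_two_at_half_life(self):
        traj = _traj(np.ones(3001), kind="intensity")
        out = correct_photobleaching(traj, PhotobleachModel(300.0))
        assert out.values[3000] == pytest.approx(2.0)

    def test_infinite_half_life_is_identity(self):
        y = np.random.default_rng(1).random(100)
        traj = _traj(y, kind="intensity")
        out = correct_photobleaching(traj, PhotobleachModel(np.inf))
        np.testing.assert_array_equal(out.values, y)

    def test_inverse_of_exponential_decay(self):
        t = np.arange(2000) * 0.1
        decayed = 1234.0 * 2.0 ** (-t / 300.0)
        traj = Trajectory(time_s=t, values=decayed, kind="intensity")
        out = correct_photobleaching(traj, PhotobleachModel(300.0))
        np.testing.assert_allclose(out.values, 1234.0, rtol=1e-12)


class TestAssociationFit:
    def test_exact_model_recovery(self):
        # k_obs = k_on c + k_off at 100 nM with the printed constants
        t = np.arange(600) * 0.1
        k = 2.1e6 * 100e-9 + 0.16
        y = 1.0 + 2.0 * (1 - np.exp(-k * t))
        fit = fit_association(Trajectory(time_s=t, values=y, kind="fold"))
        assert fit.c0 == pytest.approx(1.0, abs=1e-6)
        assert fit.c1 == pytest.approx(2.0, abs=1e-6)
        assert fit.k_obs_per_s == pytest.approx(k, abs=1e-6)

    def test_boundary_values_are_model_limits(self):
        t = np.arange(400) * 0.1
        y = 1.5 + 0.8 * (1 - np.exp(-0.5 * t))
        fit = fit_association(Trajectory(time_s=t, values=y, kind="fold"))
        assert fit.f_min == pytest.approx(1.5, abs=1e-6)
        assert fit.f_max == pytest.approx(2.3, abs=1e-6)

    @pytest.mark.parametrize("k", [0.01, 0.05, 0.2, 0.5, 1.0, 2.0])
    def test_identifiability_across_rate_range(self, k):
        dt = 0.1
        duration = max(60.0, 6.0 / k)
        t = np.arange(int(duration / dt)) * dt
        y = 1.0 + 1.5 * (1 - np.exp(-k * t))
        fit = fit_association(Trajectory(time_s=t, values=y, kind="fold"))
        assert fit.k_obs_per_s == pytest.approx(k, rel=1e-4)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            fit_association(_traj(np.ones(10)))


class TestDissociationFit:
    def test_exact_model_recovery(self):
        t = np.arange(600) * 0.1
        y = 1.0 + 2.0 * np.exp(-0.16 * t)
        fit = fit_dissociation(Trajectory(time_s=t, values=y, kind="fold"))
        assert fit.A == pytest.approx(1.0, abs=1e-6)
        assert fit.B == pytest.approx(2.0, abs=1e-6)
        assert fit.k_off_per_s == pytest.approx(0.16, abs=1e-6)
        assert fit.i_max == pytest.approx(3.0, abs=1e-6)

    def test_flat_trajectory_degenerate(self):
        fit = fit_dissociation(_traj(np.full(100, 0.7)))
        assert fit.degenerate
        assert fit.A == pytest.approx(0.7)

    def test_long_time_plateau(self):
        t = np.arange(3000) * 0.1
        y = 0.4 + 1.6 * np.exp(-0.3 * t)
        fit = fit_dissociation(Trajectory(time_s=t, values=y, kind="fold"))
        assert fit.i_min == pytest.approx(0.4, abs=1e-6)


class TestRateConstants:
    def test_exact_line_recovery(self):
        concs = [25.0, 50.0, 100.0, 150.0, 200.0]
        kobs = {c: (2.1e6 * c * 1e-9 + 0.16, 0.01) for c in concs}
        koff = {c: (0.16, 0.005) for c in [25.0, 50.0, 100.0]}
        rc = estimate_rate_constants(kobs, koff)
        assert rc.k_on_per_M_s == pytest.approx(2.1e6, rel=1e-9)
        assert rc.k_off_per_s == pytest.approx(0.16, abs=1e-12)
        assert rc.kd_nM == pytest.approx(0.16 / 2.1e6 * 1e9, rel=1e-9)

    def test_kd_is_ratio_by_construction(self):
        concs = [25.0, 50.0, 100.0]
        kobs = {c: (2.1e6 * c * 1e-9 + 0.2, 0.01) for c in concs}
        koff = {c: (0.11, 0.005) for c in concs}
        rc = estimate_rate_constants(kobs, koff)
        assert rc.kd_M == rc.k_off_per_s / rc.k_on_per_M_s

    def test_constant_koff_has_zero_slope(self):
        concs = [25.0, 50.0, 100.0, 150.0]
        kobs = {c: (2.1e6 * c * 1e-9 + 0.16, 0.01) for c in concs}
        koff = {c: (0.16, 0.005) for c in concs}
        rc = estimate_rate_constants(kobs, koff)
        assert rc.koff_slope_per_nM_s == pytest.approx(0.0, abs=1e-15)

    def test_saturating_concentrations_excluded(self):
        kobs = {c: (2.1e6 * c * 1e-9 + 0.16, 0.01)
                for c in [25.0, 50.0, 100.0, 150.0, 200.0]}
        kobs[300.0] = (0.6, 0.01)   # saturated point, off the line
        kobs[500.0] = (0.62, 0.01)
        koff = {c: (0.16, 0.005) for c in [25.0, 50.0, 100.0]}
        rc = estimate_rate_constants(kobs, koff, linear_range_max_nM=200.0)
        assert rc.k_on_per_M_s == pytest.approx(2.1e6, rel=1e-9)

    def test_two_concentrations_insufficient(self):
        kobs = {25.0: (0.2, 0.01), 50.0: (0.26, 0.01)}
        with pytest.raises(ValueError):
            estimate_rate_constants(kobs, {25.0: (0.16, 0.01)})


class TestHillFit:
    def test_half_saturation_at_kd(self):
        c = np.geomspace(1, 1000, 9)
        for n in (0.5, 1.0, 2.0):
            theta = 3.0 * c ** n / (60.0 ** n + c ** n)
            fit = fit_hill(c, theta)
            mid = fit.theta_max * fit.kd_nM ** fit.n / (
                fit.kd_nM ** fit.n + fit.kd_nM ** fit.n)
            assert mid == pytest.approx(fit.theta_max / 2)
            assert fit.kd_nM == pytest.approx(60.0, rel=1e-4)

    def test_langmuir_data_recovers_unit_coefficient(self):
        c = np.geomspace(5, 2000, 10)
        theta = 2.0 * c / (76.2 + c)
        fit = fit_hill(c, theta)
        assert fit.n == pytest.approx(1.0, abs=1e-5)
        assert fit.kd_nM == pytest.approx(76.2, rel=1e-5)

    def test_fixed_n_equals_langmuir_fit(self):
        c = np.geomspace(5, 2000, 10)
        theta = 2.0 * c / (76.2 + c)
        free = fit_hill(c, theta)
        fixed = fit_hill(c, theta, fix_n=1.0)
        assert abs(free.sse - fixed.sse) < 1e-10
        assert fixed.kd_nM == pytest.approx(76.2, rel=1e-6)

    def test_baseline_subtraction(self):
        c = np.geomspace(5, 2000, 10)
        fold = 1.0 + 2.0 * c / (76.2 + c)
        fit = fit_hill(c, fold, subtract_baseline=True)
        assert fit.theta_max == pytest.approx(2.0, rel=1e-5)

    def test_narrow_range_rejected(self):
        c = np.array([50.0, 60.0, 70.0, 80.0])
        with pytest.raises(ValueError):
            fit_hill(c, c / (c + 60.0))


class TestCompactionFit:
    def _piecewise(self, lag, rate, l0=6.0, dt=0.1, duration=12.0,
                   floor=0.5):
        t = np.arange(int(duration / dt)) * dt
        y = np.where(t < lag, l0, np.maximum(floor, l0 - rate * (t - lag)))
        return Trajectory(time_s=t, values=y, kind="length")

    def test_noiseless_exact_recovery(self):
        fit = estimate_lag_and_rate(self._piecewise(3.3, 0.51))
        assert fit.t_lag_s == pytest.approx(3.3, abs=0.1)
        assert fit.rate_um_s == pytest.approx(0.51, abs=1e-3)
        assert fit.l0_um == pytest.approx(6.0, abs=1e-6)

    def test_constant_length_is_no_compaction(self):
        fit = estimate_lag_and_rate(_traj(np.full(100, 6.0), kind="length"))
        assert fit.no_compaction

    def test_pure_decline_has_zero_lag(self):
        fit = estimate_lag_and_rate(self._piecewise(0.0, 0.4))
        assert fit.t_lag_s == pytest.approx(0.0, abs=0.1)
        assert fit.rate_um_s == pytest.approx(0.4, abs=1e-3)

    def test_floor_plateau_does_not_bias_rate(self):
        # long trajectory clamps at the tether; trimming keeps the slope
        fit = estimate_lag_and_rate(self._piecewise(3.3, 0.51, duration=40.0))
        assert fit.rate_um_s == pytest.approx(0.51, abs=5e-3)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            estimate_lag_and_rate(_traj(np.ones(10), kind="length"))
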