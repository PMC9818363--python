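"""Time-to-critical-moisture prediction, extraction and comparison."""

import logging

import numpy as np
import pytest

from powderlife import (
    EnvironmentSpec,
    IsothermFit,
    MoistureRescale,
    PackageSpec,
    PowderSpec,
    calibrate_critical_moisture,
    compare_trajectories,
    experimental_shelf_life,
    integrate_uptake,
    predict_shelf_life,
    shelf_life_lower_bound,
)
from powderlife.exceptions import DomainError, InsufficientDataError

LINEAR_FIT = IsothermFit("LINEAR", {"a": 0.2, "b": 50.0})


class TestPredict:
    def test_zero_days_when_already_critical(self, printed_package, ambient_env):
        powder = PowderSpec(0.0192, 0.005, 0.005)
        res = predict_shelf_life(LINEAR_FIT, printed_package, ambient_env, powder)
        assert res.theta_days == 0.0
        assert res.reached

    def test_constant_driving_force_limit(self, printed_package, ambient_env,
                                          nominal_powder):
        """With the isotherm frozen at aw ~= 0.28 the crossing time is the
        closed-form 0.002 / 1.7134e-4 ~= 11.67 days, a strict lower bound for
        any rising isotherm."""
        frozen = IsothermFit("LINEAR", {"a": 0.28 - 1e-9 * 0.004, "b": 1e-9})
        res = predict_shelf_life(frozen, printed_package, ambient_env, nominal_powder)
        assert res.theta_days == pytest.approx(0.002 / 1.71343458e-4, rel=1e-4)

    def test_prediction_respects_lower_bound(self, study, printed_package):
        """Every calibrated trial prediction sits above the constant-force
        bound dX*Ws/(K*Ap*p**(Rh - aw(Xi)))."""
        envs = {
            "ambient": EnvironmentSpec(25.0, 0.60, 3173.027),
            "accelerated": EnvironmentSpec(40.0, 0.90, 7380.726),
        }
        for key, res in study["predicted"].items():
            fit = study["fits"][key]
            powder = PowderSpec(0.0192, res.X_initial, res.X_critical)
            bound = shelf_life_lower_bound(fit, printed_package, envs[key[1]], powder)
            assert res.theta_days >= bound * (1 - 1e-9)

    def test_flagged_nonfinite_when_critical_above_equilibrium(
        self, printed_package, ambient_env
    ):
        powder = PowderSpec(0.0192, 0.004, 0.02)  # X* = (0.6-0.2)/50 = 0.008
        res = predict_shelf_life(LINEAR_FIT, printed_package, ambient_env, powder)
        assert not res.reached
        assert np.isinf(res.theta_days)

    def test_crossing_matches_closed_form_for_linear_isotherm(
        self, printed_package, ambient_env, nominal_powder
    ):
        c = (printed_package.permeability_K * printed_package.area_Ap
             * ambient_env.sat_pressure_pstar / nominal_powder.dry_mass_Ws)
        x_eq = (0.60 - 0.2) / 50.0
        exact = -np.log((x_eq - 0.006) / (x_eq - 0.004)) / (c * 50.0)
        res = predict_shelf_life(LINEAR_FIT, printed_package, ambient_env,
                                 nominal_powder)
        assert res.theta_days == pytest.approx(exact, abs=1e-5)


class TestExperimental:
    def test_midpoint_of_linear_segment(self):
        res = experimental_shelf_life(([0.0, 10.0], [0.004, 0.008]), 0.006)
        assert res.theta_days == pytest.approx(5.0)
        assert res.basis == "experimental"

    def test_tie_at_sampling_day_resolves_to_that_day(self):
        res = experimental_shelf_life(([0.0, 10.0, 20.0], [0.004, 0.006, 0.008]),
                                      0.006)
        assert res.theta_days == pytest.approx(10.0)

    def test_never_crossed_is_flagged(self):
        res = experimental_shelf_life(([0.0, 10.0], [0.004, 0.005]), 0.006)
        assert not res.reached

    def test_multiple_crossings_logged_first_returned(self, caplog):
        days = [0.0, 10.0, 20.0, 30.0]
        x = [0.004, 0.007, 0.005, 0.009]  # dips back below the threshold
        with caplog.at_level(logging.WARNING, logger="powderlife.shelflife"):
            res = experimental_shelf_life((days, x), 0.006)
        assert res.theta_days == pytest.approx(10.0 * 2.0 / 3.0)
        assert any("crosses" in r.message for r in caplog.records)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            experimental_shelf_life(([0.0], [0.004]), 0.006)

    def test_self_consistency_with_prediction(self, gab_fit, printed_package,
                                              ambient_env):
        """Sampling the model's own trajectory monthly puts the interpolated
        crossing within one sampling interval of the predicted crossing."""
        powder = PowderSpec(0.0192, 0.004, 0.055)
        pred = predict_shelf_life(gab_fit, printed_package, ambient_env, powder)
        days = np.arange(0.0, 301.0, 30.0)
        traj = integrate_uptake(gab_fit, printed_package, ambient_env, powder,
                                horizon=days[-1], t_eval=days)
        expr = experimental_shelf_life((days, traj.moisture_db), powder.X_critical)
        assert expr.reached and pred.reached
        assert abs(expr.theta_days - pred.theta_days) < 30.0


class TestCompare:
    def _trajectory(self, printed_package, ambient_env):
        powder = PowderSpec(0.0192, 0.004, 0.0079)
        return integrate_uptake(LINEAR_FIT, printed_package, ambient_env, powder,
                                horizon=200.0)

    def test_exact_samples_give_perfect_agreement(self, printed_package, ambient_env):
        traj = self._trajectory(printed_package, ambient_env)
        days = np.linspace(0, 180, 8)
        comp = compare_trajectories(traj, (days, traj.moisture_at(days)))
        assert comp["pearson_r"] == pytest.approx(1.0, abs=1e-12)
        assert comp["rmse"] == pytest.approx(0.0, abs=1e-15)
        assert comp["n"] == 8

    def test_noisy_samples_keep_high_correlation(self, printed_package, ambient_env,
                                                 rng):
        traj = self._trajectory(printed_package, ambient_env)
        days = np.linspace(0, 180, 8)
        x = np.asarray(traj.moisture_at(days))
        noisy = x + 0.02 * (x.max() - x.min()) * rng.standard_normal(len(x))
        comp = compare_trajectories(traj, (days, noisy))
        assert comp["pearson_r"] > 0.95

    def test_too_few_pairs(self, printed_package, ambient_env):
        traj = self._trajectory(printed_package, ambient_env)
        with pytest.raises(InsufficientDataError):
            compare_trajectories(traj, ([0.0, 10.0], [0.004, 0.005]))

    def test_observation_beyond_horizon_rejected(self, printed_package, ambient_env):
        traj = self._trajectory(printed_package, ambient_env)
        with pytest.raises(DomainError):
            compare_trajectories(traj, ([0.0, 10.0, 500.0], [0.004, 0.005, 0.006]))


class TestCalibration:
    def test_rescale_round_trip(self):
        r = MoistureRescale(0.004, 0.006, 0.0594, 0.0639)
        v = np.array([0.004, 0.005, 0.006])
        assert np.allclose(r.to_band(r.to_data(v)), v)
        assert r.to_data(0.004) == pytest.approx(0.0594)
        assert r.to_data(0.006) == pytest.approx(0.0639)

    def test_recovers_known_threshold_from_stated_days(self):
        """Two synthetic series whose stated crossings come from a known
        threshold: the calibration must return that threshold."""
        days = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
        s1 = (days, 0.0594 + 1e-4 * days)
        s2 = (days, 0.0594 + 5e-5 * days)
        xc_true = 0.0654
        stated = {
            "a": float(np.interp(xc_true, s1[1], days)),
            "b": float(np.interp(xc_true, s2[1], days)),
        }
        xc = calibrate_critical_moisture({"a": s1, "b": s2}, stated)
        assert xc == pytest.approx(xc_true, abs=1e-5)

    def test_trial_calibration_reproduces_stated_days(self, study, trial):
        """The calibrated common critical moisture puts every measured
        series' first crossing within six days of its stated shelf life."""
        from powderlife.datasets import STATED_EXPERIMENTAL_DAYS

        xc = study["critical_moisture_db"]
        for key, stated in STATED_EXPERIMENTAL_DAYS.items():
            got = experimental_shelf_life(trial[key], xc).theta_days
            assert got == pytest.approx(stated, abs=6.0), key
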