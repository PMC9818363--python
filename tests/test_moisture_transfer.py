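"""Package moisture-balance rate, integration and saturation pressure."""

import math

import numpy as np
import pytest

from powderlife import (
    EnvironmentSpec,
    IsothermFit,
    PackageSpec,
    PowderSpec,
    equilibrium_moisture,
    integrate_uptake,
    isotherm_aw,
    saturation_pressure,
    uptake_rate,
)
from powderlife.exceptions import DomainError

LINEAR_FIT = IsothermFit("LINEAR", {"a": 0.2, "b": 50.0})  # aw = 0.2 + 50 X


def linear_closed_form(t, pkg, env, powder, a=0.2, b=50.0):
    """Exponential solution for a linear isotherm: the balance becomes
    dX/dt = c*(Rh - a - b*X) with c = K*Ap*p*/Ws."""
    c = pkg.permeability_K * pkg.area_Ap * env.sat_pressure_pstar / powder.dry_mass_Ws
    x_eq = (env.rel_humidity_Rh - a) / b
    return x_eq + (powder.X_initial - x_eq) * np.exp(-c * b * np.asarray(t))


class TestUptakeRate:
    def test_printed_constants_ambient(self, printed_package, ambient_env,
                                       nominal_powder):
        """(5.4e-8 * 0.0600 * 3173.027 / 0.0192) * (0.60 - 0.28) kg/kg/day."""
        fit = IsothermFit("LINEAR", {"a": 0.28 - 50.0 * 0.004, "b": 50.0})
        r = uptake_rate(0.004, fit, printed_package, ambient_env, nominal_powder)
        assert r == pytest.approx(1.71343e-4, rel=1e-4)

    def test_printed_constants_accelerated(self, printed_package, accelerated_env,
                                           nominal_powder):
        fit = IsothermFit("LINEAR", {"a": 0.28 - 50.0 * 0.004, "b": 50.0})
        r = uptake_rate(0.004, fit, printed_package, accelerated_env, nominal_powder)
        assert r == pytest.approx(7.722e-4, rel=1e-3)

    def test_zero_at_equilibrium(self, printed_package, ambient_env, nominal_powder):
        x_eq = (0.60 - 0.2) / 50.0
        r = uptake_rate(x_eq, LINEAR_FIT, printed_package, ambient_env, nominal_powder)
        assert r == pytest.approx(0.0, abs=1e-15)

    def test_sign_matches_driving_force(self, printed_package, ambient_env,
                                        nominal_powder):
        x_eq = (0.60 - 0.2) / 50.0
        below = uptake_rate(x_eq * 0.5, LINEAR_FIT, printed_package, ambient_env,
                            nominal_powder)
        above = uptake_rate(x_eq * 1.5, LINEAR_FIT, printed_package, ambient_env,
                            nominal_powder)
        assert below > 0 > above


class TestIntegration:
    def test_linear_isotherm_matches_closed_form(self, printed_package, ambient_env,
                                                 nominal_powder):
        t = np.linspace(0, 200, 201)
        traj = integrate_uptake(LINEAR_FIT, printed_package, ambient_env,
                                nominal_powder, horizon=200.0, t_eval=t,
                                rtol=1e-11, atol=1e-14)
        exact = linear_closed_form(t, printed_package, ambient_env, nominal_powder)
        assert np.allclose(traj.moisture_db, exact, rtol=1e-8)

    def test_equilibrium_start_stays_constant(self, printed_package, ambient_env):
        x_eq = (0.60 - 0.2) / 50.0
        powder = PowderSpec(0.0192, x_eq, x_eq + 0.01)
        traj = integrate_uptake(LINEAR_FIT, printed_package, ambient_env, powder,
                                horizon=100.0)
        assert np.allclose(traj.moisture_db, x_eq, rtol=1e-10)

    def test_no_overshoot_of_equilibrium(self, gab_fit, printed_package, ambient_env):
        powder = PowderSpec(0.0192, 0.004, 0.2)
        x_eq = equilibrium_moisture(gab_fit, ambient_env)
        traj = integrate_uptake(gab_fit, printed_package, ambient_env, powder,
                                horizon=3000.0)
        assert np.all(traj.moisture_db <= x_eq * (1 + 1e-8))
        assert np.all(np.diff(traj.moisture_db) >= -1e-12)

    def test_predicted_trajectory_aw_consistent_with_isotherm(
        self, gab_fit, printed_package, ambient_env
    ):
        powder = PowderSpec(0.0192, 0.004, 0.2)
        traj = integrate_uptake(gab_fit, printed_package, ambient_env, powder,
                                horizon=50.0)
        expected = np.array([isotherm_aw(gab_fit, x) for x in traj.moisture_db])
        assert np.allclose(traj.water_activity, expected, rtol=1e-12)

    def test_agrees_with_fixed_step_rk4(self, gab_fit, printed_package, ambient_env):
        """Independent oracle: classic RK4 at h = 0.01 day."""
        powder = PowderSpec(0.0192, 0.004, 0.2)
        xm, c_par, k = (gab_fit.params[n] for n in ("Xm", "C", "k"))
        c = (printed_package.permeability_K * printed_package.area_Ap
             * ambient_env.sat_pressure_pstar / powder.dry_mass_Ws)
        rh = ambient_env.rel_humidity_Rh

        def aw_of_x(x):
            if x == 0:
                return 0.0
            a2 = x * (c_par - 1.0)
            a1 = -(x * (c_par - 2.0) - xm * c_par)
            disc = math.sqrt(a1 * a1 + 4.0 * a2 * x)
            return (-a1 + disc) / (2.0 * a2) / k

        def f(x):
            return c * (rh - aw_of_x(x))

        h, x = 0.01, powder.X_initial
        record = {0.0: x}
        for i in range(20000):
            k1 = f(x)
            k2 = f(x + 0.5 * h * k1)
            k3 = f(x + 0.5 * h * k2)
            k4 = f(x + h * k3)
            x += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            record[round((i + 1) * h, 6)] = x
        t_eval = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
        traj = integrate_uptake(gab_fit, printed_package, ambient_env, powder,
                                horizon=200.0, t_eval=t_eval, rtol=1e-10, atol=1e-12)
        oracle = np.array([record[t] for t in t_eval])
        assert np.allclose(traj.moisture_db, oracle, rtol=1e-6)

    def test_monotone_response_to_transfer_parameters(self, gab_fit, rng):
        """Raising Rh, p*, K or Ap (others fixed) never lowers X at any time."""
        powder = PowderSpec(0.0192, 0.004, 0.2)
        t = np.linspace(0, 120, 61)
        base_kw = {"K": 5.4e-8, "Ap": 0.06, "Rh": 0.60, "pstar": 3173.027}

        def run(kw):
            pkg = PackageSpec(permeability_K=kw["K"], area_Ap=kw["Ap"])
            env = EnvironmentSpec(25.0, kw["Rh"], kw["pstar"])
            return integrate_uptake(gab_fit, pkg, env, powder, horizon=120.0,
                                    t_eval=t).moisture_db

        base = run(base_kw)
        for name in base_kw:
            factor = 1.0 + rng.uniform(0.05, 0.5)
            kw = dict(base_kw)
            kw[name] = min(base_kw[name] * factor, 0.99 if name == "Rh" else np.inf)
            assert np.all(run(kw) >= base - 1e-10), name

    def test_invalid_horizon(self, gab_fit, printed_package, ambient_env,
                             nominal_powder):
        with pytest.raises(DomainError):
            integrate_uptake(gab_fit, printed_package, ambient_env, nominal_powder,
                             horizon=0.0)


class TestSaturationPressure:
    def test_steam_table_values(self):
        assert saturation_pressure(25.0) == 3173.027
        assert saturation_pressure(40.0) == 7380.726

    def test_correlation_at_30C(self):
        assert saturation_pressure(30.0) == pytest.approx(4246.0, rel=0.02)

    @pytest.mark.parametrize("t", [-5.0, 0.0, 100.0, 150.0])
    def test_domain(self, t):
        with pytest.raises(DomainError):
            saturation_pressure(t)


class TestSpecValidation:
    def test_package_area_from_dims(self):
        pkg = PackageSpec(permeability_K=5.4e-8, width=0.155, height=0.193)
        assert pkg.area_Ap == pytest.approx(2 * 0.155 * 0.193)

    def test_package_requires_area_or_dims(self):
        with pytest.raises(DomainError):
            PackageSpec(permeability_K=5.4e-8)

    @pytest.mark.parametrize("rh", [0.0, -0.2, 1.5])
    def test_environment_humidity_bounds(self, rh):
        with pytest.raises(DomainError):
            EnvironmentSpec(25.0, rh, 3173.027)

    def test_environment_defaults_pstar(self):
        env = EnvironmentSpec(25.0, 0.6)
        assert env.sat_pressure_pstar == 3173.027

    def test_powder_critical_below_initial_rejected(self):
        with pytest.raises(DomainError):
            PowderSpec(0.0192, 0.006, 0.004)
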