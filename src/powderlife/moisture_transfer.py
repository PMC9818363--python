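"""Package moisture-balance model for powder in a permeable pouch.

A powder of dry mass ``Ws`` sealed in a film of water-vapour permeability
``K`` and area ``Ap`` exchanges moisture with a storage environment at
relative humidity ``Rh`` and saturation vapour pressure ``p*``.  The lumped
mass balance is

    Ws * dX/dtheta = K * Ap * p* * (Rh - aw(X))

where ``X`` is the dry-basis moisture content, ``theta`` is storage time in
days and ``aw(X)`` is the powder's sorption isotherm.  Moisture rises
(falls) while the film-side humidity exceeds (trails) the powder's water
activity and equilibrates at ``X*`` with ``aw(X*) = Rh``.

Units: K in kg water / m^2 / day / Pa, Ap in m^2, p* in Pa, Ws in kg, X in
kg/kg dry solids, time in days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DomainError, PowderlifeError
from .isotherms import IsothermFit, isotherm_aw, isotherm_moisture

__all__ = [
    "PackageSpec",
    "EnvironmentSpec",
    "PowderSpec",
    "MoistureTrajectory",
    "saturation_pressure",
    "uptake_rate",
    "integrate_uptake",
    "equilibrium_moisture",
]

log = logging.getLogger(__name__)

#: steam-table saturation pressures (Pa) at the two study temperatures
_STEAM_TABLE = {25.0: 3173.027, 40.0: 7380.726}

#: water activity is clamped to this interval before the driving force
_AW_CLAMP = (0.0, 0.9999)


def saturation_pressure(temperature_c: float) -> float:
    """Saturation vapour pressure of water (Pa) at ``temperature_c``.

    At 25 and 40 degrees C the tabulated steam-table values 3173.027 and
    7380.726 Pa are returned verbatim; elsewhere the Arden Buck correlation
    is used (within ~0.1% of steam tables over 0-100 C) and the
    interpolation is logged.
    """
    t = float(temperature_c)
    if not 0.0 < t < 100.0:
        raise DomainError(f"temperature must lie in (0, 100) C, got {t}")
    if t in _STEAM_TABLE:
        return _STEAM_TABLE[t]
    p = 611.21 * np.exp((18.678 - t / 234.5) * t / (257.14 + t))
    log.info("saturation_pressure(%.3g C) interpolated from Buck correlation: %.4g Pa", t, p)
    return float(p)


@dataclass(frozen=True)
class PackageSpec:
    """Water-vapour barrier properties of the package.

    ``area_Ap`` may be given directly, or derived from pouch ``width`` and
    ``height`` (both in m) times the number of permeating ``faces``.
    """

    permeability_K: float  # kg water / m^2 / day / Pa
    area_Ap: float | None = None  # m^2
    width: float | None = None
    height: float | None = None
    faces: int = 2

    def __post_init__(self):
        if self.permeability_K <= 0:
            raise DomainError("permeability_K must be > 0")
        if self.area_Ap is None:
            if self.width is None or self.height is None:
                raise DomainError("give area_Ap or both width and height")
            object.__setattr__(self, "area_Ap", self.faces * self.width * self.height)
        if self.area_Ap <= 0:
            raise DomainError("area_Ap must be > 0")


@dataclass(frozen=True)
class EnvironmentSpec:
    """Storage environment: temperature (C), relative humidity (fraction),
    and saturation pressure (Pa, defaulted from :func:`saturation_pressure`)."""

    temperature_T: float
    rel_humidity_Rh: float
    sat_pressure_pstar: float | None = None

    def __post_init__(self):
        if not 0.0 < self.rel_humidity_Rh <= 1.0:
            raise DomainError("rel_humidity_Rh must lie in (0, 1]")
        if self.sat_pressure_pstar is None:
            object.__setattr__(
                self, "sat_pressure_pstar", saturation_pressure(self.temperature_T)
            )
        if self.sat_pressure_pstar <= 0:
            raise DomainError("sat_pressure_pstar must be > 0")


@dataclass(frozen=True)
class PowderSpec:
    """Powder charge: dry mass (kg), initial and critical dry-basis moisture."""

    dry_mass_Ws: float
    X_initial: float
    X_critical: float

    def __post_init__(self):
        if self.dry_mass_Ws <= 0:
            raise DomainError("dry_mass_Ws must be > 0")
        if self.X_initial < 0:
            raise DomainError("X_initial must be >= 0")
        if self.X_critical < self.X_initial:
            raise DomainError("X_critical must be >= X_initial")


@dataclass
class MoistureTrajectory:
    """Moisture content and water activity along storage time.

    ``provenance`` is one of ``predicted``, ``synthetic`` or
    ``experimental``.  Predicted trajectories built by
    :func:`integrate_uptake` carry a dense interpolant, exposed through
    :meth:`moisture_at`.
    """

    times: np.ndarray  # days, strictly increasing from 0
    moisture_db: np.ndarray
    water_activity: np.ndarray
    provenance: str = "predicted"
    _dense: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.moisture_db = np.asarray(self.moisture_db, dtype=float)
        self.water_activity = np.asarray(self.water_activity, dtype=float)
        if not (len(self.times) == len(self.moisture_db) == len(self.water_activity)):
            raise DomainError("trajectory arrays must have equal length")
        if len(self.times) and (self.times[0] < 0 or np.any(np.diff(self.times) <= 0)):
            raise DomainError("times must be strictly increasing and start at >= 0")
        if self.provenance not in ("predicted", "synthetic", "experimental"):
            raise DomainError(f"unknown provenance {self.provenance!r}")

    def moisture_at(self, t):
        """Moisture at time(s) ``t``, using the dense solver output when
        available and linear interpolation otherwise."""
        t = np.asarray(t, dtype=float)
        if self._dense is not None:
            out = np.atleast_2d(self._dense(t))[0]
        else:
            out = np.interp(t, self.times, self.moisture_db)
        out = np.asarray(out)
        return float(out.reshape(-1)[0]) if t.ndim == 0 else out

    @property
    def horizon(self) -> float:
        return float(self.times[-1])


def _clamped_aw(fit: IsothermFit, x: float) -> float:
    aw = isotherm_aw(fit, max(float(x), 0.0))
    lo, hi = _AW_CLAMP
    if aw < lo or aw > hi:
        log.debug("clamping aw=%.6g to [%g, %g]", aw, lo, hi)
        aw = min(max(aw, lo), hi)
    return aw


def uptake_rate(
    x: float,
    fit: IsothermFit,
    pkg: PackageSpec,
    env: EnvironmentSpec,
    powder: PowderSpec,
) -> float:
    """Instantaneous moisture uptake rate dX/dtheta (kg/kg/day) at moisture ``x``.

    Equals ``K*Ap*p*/Ws * (Rh - aw(x))``: positive while the environment is
    more humid than the powder surface, zero at equilibrium.
    """
    aw = _clamped_aw(fit, x)
    c = pkg.permeability_K * pkg.area_Ap * env.sat_pressure_pstar / powder.dry_mass_Ws
    return c * (env.rel_humidity_Rh - aw)


def equilibrium_moisture(fit: IsothermFit, env: EnvironmentSpec) -> float:
    """Moisture ``X*`` in equilibrium with the environment, ``aw(X*) = Rh``.

    Returns ``inf`` when the isotherm cannot reach ``Rh`` (e.g. a GAB pole
    below it).
    """
    rh = min(env.rel_humidity_Rh, _AW_CLAMP[1])
    try:
        return float(isotherm_moisture(fit, rh))
    except DomainError:
        return float("inf")


def integrate_uptake(
    fit: IsothermFit,
    pkg: PackageSpec,
    env: EnvironmentSpec,
    powder: PowderSpec,
    horizon: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float | None = None,
) -> MoistureTrajectory:
    """Integrate the package moisture balance over ``[0, horizon]`` days.

    Adaptive Runge-Kutta (RK45) with dense output; absolute tolerance 1e-10
    on X by default.  The returned trajectory starts at ``powder.X_initial``,
    is monotone while ``aw < Rh`` and approaches the equilibrium moisture
    ``X*`` without overshoot (to solver tolerance).
    """
    if horizon <= 0:
        raise DomainError("horizon must be > 0 days")
    x_eq = equilibrium_moisture(fit, env)

    def rhs(t, y):
        x = min(y[0], x_eq) if np.isfinite(x_eq) else y[0]
        return [uptake_rate(x, fit, pkg, env, powder)]

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 501)
    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        [powder.X_initial],
        t_eval=np.asarray(t_eval, dtype=float),
        dense_output=True,
        rtol=rtol,
        atol=atol,
        max_step=max_step if max_step is not None else np.inf,
    )
    if not sol.success:
        raise PowderlifeError(
            f"moisture integration failed at t={sol.t[-1] if len(sol.t) else 0:.3g} d: "
            f"{sol.message}"
        )
    x = np.clip(sol.y[0], 0.0, x_eq if np.isfinite(x_eq) else None)
    aw = np.array([_clamped_aw(fit, xi) for xi in x])
    return MoistureTrajectory(
        times=sol.t,
        moisture_db=x,
        water_activity=aw,
        provenance="predicted",
        _dense=sol.sol,
    )
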