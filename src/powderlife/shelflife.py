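"""Shelf-life estimation: time for packaged powder to reach critical moisture.

Shelf life is the storage time ``theta`` at which the dry-basis moisture
``X(theta)`` of the packaged powder first reaches its critical value ``Xc``.
The predicted value comes from integrating the package moisture balance
(:mod:`powderlife.moisture_transfer`) under a fitted sorption isotherm and
locating the crossing by root-finding on the dense solution; the
experimental value is the first crossing of ``Xc`` by a measured storage
series, linearly interpolated between sampling days.  When ``Xc`` lies at or
above the environmental equilibrium moisture ``X*`` (``aw(X*) = Rh``) the
powder never reaches it and the result is flagged non-finite rather than
raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import pearsonr

from .exceptions import DomainError, InsufficientDataError
from .isotherms import IsothermFit, isotherm_aw
from .moisture_transfer import (
    EnvironmentSpec,
    MoistureTrajectory,
    PackageSpec,
    PowderSpec,
    equilibrium_moisture,
    integrate_uptake,
    uptake_rate,
)

__all__ = [
    "ShelfLifeResult",
    "predict_shelf_life",
    "experimental_shelf_life",
    "compare_trajectories",
    "shelf_life_lower_bound",
    "MoistureRescale",
    "calibrate_critical_moisture",
]

log = logging.getLogger(__name__)

#: root-finding tolerance on the crossing time, days
CROSSING_TOL_DAYS = 1e-6


@dataclass
class ShelfLifeResult:
    """Time to critical moisture, with provenance.

    ``theta_days`` is ``inf`` (and ``reached`` False) when the critical
    moisture lies at or above the environmental equilibrium and is never
    attained.
    """

    theta_days: float
    basis: str  # "predicted" | "experimental"
    X_initial: float
    X_critical: float
    treatment: str | None = None
    condition: str | None = None
    trajectory: MoistureTrajectory | None = None

    def __post_init__(self):
        if self.basis not in ("predicted", "experimental"):
            raise DomainError(f"unknown basis {self.basis!r}")
        if np.isfinite(self.theta_days) and self.theta_days < 0:
            raise DomainError("theta_days must be >= 0")

    @property
    def reached(self) -> bool:
        return bool(np.isfinite(self.theta_days))

    def to_dict(self) -> dict:
        return {
            "theta_days": None if not self.reached else float(self.theta_days),
            "reached": self.reached,
            "basis": self.basis,
            "X_initial": self.X_initial,
            "X_critical": self.X_critical,
            "treatment": self.treatment,
            "condition": self.condition,
        }


def shelf_life_lower_bound(
    fit: IsothermFit, pkg: PackageSpec, env: EnvironmentSpec, powder: PowderSpec
) -> float:
    """Constant-driving-force bound ``dX*Ws / (K*Ap*p**(Rh - aw(Xi)))``.

    The true shelf life can never be shorter: along the trajectory the
    powder's water activity only rises, so the driving force only shrinks
    below its initial value.
    """
    r0 = uptake_rate(powder.X_initial, fit, pkg, env, powder)
    if r0 <= 0:
        return float("inf")
    return (powder.X_critical - powder.X_initial) / r0


def predict_shelf_life(
    fit: IsothermFit,
    pkg: PackageSpec,
    env: EnvironmentSpec,
    powder: PowderSpec,
    treatment: str | None = None,
    condition: str | None = None,
    max_horizon: float = 1e6,
) -> ShelfLifeResult:
    """Predicted time for moisture to rise from ``X_initial`` to ``X_critical``.

    Integrates the moisture balance with dense output and locates
    ``X(theta) = Xc`` by bracketing + Brent root refinement to 1e-6 day.
    Returns a flagged non-finite result when ``Xc`` is at or above the
    equilibrium moisture ``X*``.
    """
    xi, xc = powder.X_initial, powder.X_critical
    if xc <= xi:
        traj = MoistureTrajectory(np.array([0.0, 1.0]), np.full(2, xi),
                                  np.full(2, isotherm_aw(fit, xi)))
        return ShelfLifeResult(0.0, "predicted", xi, xc, treatment, condition, traj)

    x_eq = equilibrium_moisture(fit, env)
    if xc >= x_eq:
        log.info(
            "X_critical %.4g at/above equilibrium moisture %.4g: never reached",
            xc, x_eq,
        )
        return ShelfLifeResult(float("inf"), "predicted", xi, xc, treatment, condition)

    horizon = 4.0 * shelf_life_lower_bound(fit, pkg, env, powder)
    traj = None
    while horizon <= max_horizon:
        traj = integrate_uptake(fit, pkg, env, powder, horizon)
        if traj.moisture_db[-1] >= xc:
            break
        horizon *= 4.0
    if traj is None or traj.moisture_db[-1] < xc:
        return ShelfLifeResult(float("inf"), "predicted", xi, xc, treatment, condition,
                               traj)
    idx = int(np.searchsorted(traj.moisture_db >= xc, True))
    hi = traj.times[idx]
    lo = traj.times[idx - 1] if idx > 0 else 0.0
    theta = brentq(lambda t: traj.moisture_at(t) - xc, lo, hi,
                   xtol=CROSSING_TOL_DAYS)
    return ShelfLifeResult(float(theta), "predicted", xi, xc, treatment, condition,
                           traj)


def _series_days_moisture(series):
    """Accept a StorageSeries-like object or a (days, moisture_db) pair."""
    if hasattr(series, "days") and hasattr(series, "moisture_db"):
        m = series.moisture_db
        return np.asarray(series.days, float), np.asarray(m() if callable(m) else m, float)
    days, x = series
    return np.asarray(days, float), np.asarray(x, float)


def experimental_shelf_life(
    series,
    X_critical: float,
    treatment: str | None = None,
    condition: str | None = None,
) -> ShelfLifeResult:
    """First crossing of ``X_critical`` by a measured moisture series.

    ``series`` is a :class:`~powderlife.io.StorageSeries` or a
    ``(days, moisture_db)`` pair with moisture already on the dry basis.
    The crossing time is linearly interpolated between adjacent sampling
    days; a tie at a sampling day resolves to that day.  Non-monotone series
    may cross more than once: the first crossing is returned and the others
    are logged.
    """
    days, x = _series_days_moisture(series)
    if len(days) < 2:
        raise InsufficientDataError("need at least 2 time points")
    if np.any(np.diff(days) <= 0):
        raise DomainError("sampling days must be strictly increasing")

    crossings = []
    if x[0] >= X_critical:
        crossings.append(float(days[0]))
    for i in range(1, len(x)):
        if x[i - 1] < X_critical <= x[i]:
            frac = (X_critical - x[i - 1]) / (x[i] - x[i - 1])
            crossings.append(float(days[i - 1] + frac * (days[i] - days[i - 1])))
    if not crossings:
        theta = float("inf")
    else:
        theta = crossings[0]
        if len(crossings) > 1:
            log.warning(
                "series crosses X_critical %d times (at days %s); using the first",
                len(crossings), np.round(crossings, 2),
            )
    traj = MoistureTrajectory(days, x, np.full_like(x, np.nan),
                              provenance="experimental") if days[0] == 0 else None
    return ShelfLifeResult(theta, "experimental", float(x[0]), float(X_critical),
                           treatment, condition, traj)


def compare_trajectories(predicted: MoistureTrajectory, series) -> dict:
    """Pair a predicted trajectory with observed moisture at the sampling days.

    Returns ``{"pearson_r", "rmse", "n", "pairs"}`` where ``pairs`` is a
    DataFrame of (day, predicted, observed) and RMSE is in kg/kg dry basis.
    """
    days, x_obs = _series_days_moisture(series)
    if len(days) < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if days[-1] > predicted.horizon * (1 + 1e-9):
        raise DomainError(
            f"observed day {days[-1]} beyond predicted horizon {predicted.horizon}"
        )
    x_pred = np.asarray(predicted.moisture_at(days))
    if np.std(x_pred) == 0 or np.std(x_obs) == 0:
        r = float("nan")
    else:
        r = float(pearsonr(x_pred, x_obs).statistic)
    rmse = float(np.sqrt(np.mean((x_pred - x_obs) ** 2)))
    pairs = pd.DataFrame({"day": days, "predicted": x_pred, "observed": x_obs})
    return {"pearson_r": r, "rmse": rmse, "n": len(days), "pairs": pairs}


# ---------------------------------------------------------------------------
# mapping a nominal [Xi, Xc] band onto the data's dry-basis scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoistureRescale:
    """Affine map between a nominal moisture band and the dry-basis scale.

    Storage studies often quote initial/critical moisture on a nominal scale
    (here ``Xi``/``Xc``) that does not coincide with the dry-basis values of
    the measured series.  This map sends the nominal band
    ``[band_lo, band_hi]`` onto ``[data_lo, data_hi]`` affinely, so
    ``to_data(band_lo) == data_lo`` and ``to_data(band_hi) == data_hi``.
    """

    band_lo: float
    band_hi: float
    data_lo: float
    data_hi: float

    def __post_init__(self):
        if self.band_hi <= self.band_lo or self.data_hi <= self.data_lo:
            raise DomainError("rescale bands must have positive width")

    @property
    def scale(self) -> float:
        return (self.data_hi - self.data_lo) / (self.band_hi - self.band_lo)

    def to_data(self, v):
        return self.data_lo + (np.asarray(v, float) - self.band_lo) * self.scale

    def to_band(self, x):
        return self.band_lo + (np.asarray(x, float) - self.data_lo) / self.scale


def calibrate_critical_moisture(
    series_map: dict,
    stated_days: dict,
    bounds: tuple[float, float] = (0.060, 0.075),
) -> float:
    """Recover a common critical dry-basis moisture from stated shelf lives.

    Given measured series and the stated experimental shelf life of each,
    find the single threshold ``Xc_db`` whose first-crossing days (linear
    interpolation, :func:`experimental_shelf_life`) best reproduce the
    stated days in least squares.  Series whose crossing is non-finite at a
    candidate threshold incur a large penalty, which keeps the optimum
    inside the attainable range.
    """
    keys = [k for k in series_map if k in stated_days]
    if not keys:
        raise InsufficientDataError("no series with stated shelf lives")
    prepared = {k: _series_days_moisture(series_map[k]) for k in keys}

    def loss(xc):
        tot = 0.0
        for k in keys:
            res = experimental_shelf_life(prepared[k], xc)
            tot += (res.theta_days - stated_days[k]) ** 2 if res.reached else 1e6
        return tot

    res = minimize_scalar(loss, bounds=bounds, method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)
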