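"""Moisture sorption isotherms for low-moisture food powders.

An isotherm links the equilibrium dry-basis moisture content ``X`` (kg water
per kg dry solids) of a material to the water activity ``aw`` of its
surroundings at fixed temperature.  The workhorse here is the
Guggenheim-Anderson-de Boer (GAB) model,

    X(aw) = Xm * C * k * aw / [(1 - k*aw) * (1 - k*aw + C*k*aw)]

with monolayer moisture ``Xm`` (kg/kg), energy constant ``C > 0`` and
correction factor ``0 < k < 1``; it is the standard multilayer description of
food sorption up to aw of about 0.94.  The two-parameter Halsey, Oswin and
Iglesias-Chirife families and a linear isotherm (``aw = a + b*X``) are
provided for model comparison and as analytically tractable surrogates.

All internal moisture values are DRY basis; wet-basis percentages convert via
``X = m / (100 - m)`` (see :func:`wet_basis_to_dry`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DomainError, FitFailureError, InsufficientDataError, RangeError

__all__ = [
    "GAB",
    "HALSEY",
    "OSWIN",
    "IGLESIAS_CHIRIFE",
    "LINEAR",
    "FAMILIES",
    "SorptionPoint",
    "IsothermFit",
    "isotherm_moisture",
    "isotherm_aw",
    "fit_isotherm",
    "wet_basis_to_dry",
    "dry_to_wet_basis",
]

GAB = "GAB"
HALSEY = "HALSEY"
OSWIN = "OSWIN"
IGLESIAS_CHIRIFE = "IGLESIAS_CHIRIFE"
LINEAR = "LINEAR"

#: parameter names per family, in fitting order
_PARAM_NAMES = {
    GAB: ("Xm", "C", "k"),
    HALSEY: ("A", "B"),
    OSWIN: ("A", "B"),
    IGLESIAS_CHIRIFE: ("A", "B"),
    LINEAR: ("a", "b"),
}
FAMILIES = tuple(_PARAM_NAMES)

#: box constraints used by :func:`fit_isotherm`
_BOUNDS = {
    GAB: ([1e-8, 1e-6, 1e-3], [1.0, 1e4, 0.999]),
    HALSEY: ([1e-10, 1e-3], [1e3, 20.0]),
    OSWIN: ([1e-10, 1e-3], [10.0, 10.0]),
    IGLESIAS_CHIRIFE: ([0.0, 1e-10], [0.999, 10.0]),
    LINEAR: ([-10.0, 1e-8], [1.0, 1e4]),
}

#: upper end of the GAB validity range in aw
GAB_VALIDITY_AW = 0.94


def wet_basis_to_dry(moisture_pct_wb):
    """Convert wet-basis moisture percent ``m`` to dry basis ``m/(100-m)``."""
    m = np.asarray(moisture_pct_wb, dtype=float)
    if np.any(m < 0) or np.any(m >= 100):
        raise DomainError("wet-basis moisture percent must lie in [0, 100)")
    out = m / (100.0 - m)
    return float(out) if out.ndim == 0 else out


def dry_to_wet_basis(moisture_db):
    """Convert dry-basis moisture ``X`` to wet-basis percent ``100*X/(1+X)``."""
    x = np.asarray(moisture_db, dtype=float)
    if np.any(x < 0):
        raise DomainError("dry-basis moisture must be non-negative")
    out = 100.0 * x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SorptionPoint:
    """One equilibrium (moisture, water-activity) observation.

    Parameters
    ----------
    moisture_db:
        Moisture content, kg water per kg dry solids (>= 0).
    water_activity:
        Dimensionless water activity in [0, 1).
    temperature:
        Temperature label in degrees Celsius.
    """

    moisture_db: float
    water_activity: float
    temperature: float = 25.0

    def __post_init__(self):
        if self.moisture_db < 0:
            raise DomainError(f"moisture_db must be >= 0, got {self.moisture_db}")
        if not 0.0 <= self.water_activity < 1.0:
            raise DomainError(
                f"water_activity must lie in [0, 1), got {self.water_activity}"
            )


@dataclass
class IsothermFit:
    """A fitted (or constructed) sorption isotherm.

    ``params`` maps parameter names to values; names per family are
    ``GAB: Xm, C, k``, ``HALSEY/OSWIN/IGLESIAS_CHIRIFE: A, B`` and
    ``LINEAR: a, b`` (for ``aw = a + b*X``).
    """

    family: str
    params: dict[str, float]
    temperature: float = 25.0
    rss: float | None = None
    n_points: int | None = None
    series: str | None = None  # optional provenance label

    def __post_init__(self):
        if self.family not in _PARAM_NAMES:
            raise DomainError(f"unknown isotherm family {self.family!r}")
        missing = set(_PARAM_NAMES[self.family]) - set(self.params)
        if missing:
            raise DomainError(f"{self.family} fit missing parameters {sorted(missing)}")
        if self.family == GAB:
            xm, c, k = (self.params[n] for n in ("Xm", "C", "k"))
            if not (xm > 0 and c > 0 and 0 < k < 1):
                raise DomainError(
                    f"GAB parameters must satisfy Xm>0, C>0, 0<k<1; got "
                    f"Xm={xm}, C={c}, k={k}"
                )
        elif self.family == LINEAR and self.params["b"] <= 0:
            raise DomainError("LINEAR isotherm requires slope b > 0")

    @property
    def param_vector(self) -> np.ndarray:
        return np.array([self.params[n] for n in _PARAM_NAMES[self.family]])

    def moisture(self, aw):
        return isotherm_moisture(self, aw)

    def water_activity(self, x):
        return isotherm_aw(self, x)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "temperature": self.temperature,
            "rss": self.rss,
            "n_points": self.n_points,
            "series": self.series,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsothermFit":
        return cls(
            family=d["family"],
            params={k: float(v) for k, v in d["params"].items()},
            temperature=d.get("temperature", 25.0),
            rss=d.get("rss"),
            n_points=d.get("n_points"),
            series=d.get("series"),
        )


# ---------------------------------------------------------------------------
# forward evaluation X(aw)
# ---------------------------------------------------------------------------

def _gab_x(aw, xm, c, k):
    kaw = k * aw
    return xm * c * kaw / ((1.0 - kaw) * (1.0 - kaw + c * kaw))


def _family_x(family, params, aw):
    aw = np.asarray(aw, dtype=float)
    if family == GAB:
        return _gab_x(aw, params["Xm"], params["C"], params["k"])
    if family == HALSEY:
        # aw = exp(-A / X**B)
        a, b = params["A"], params["B"]
        with np.errstate(divide="ignore"):
            ln = np.log(aw)
        return np.where(aw > 0, (-a / np.where(ln < 0, ln, -np.inf)) ** (1.0 / b), 0.0)
    if family == OSWIN:
        return params["A"] * (aw / (1.0 - aw)) ** params["B"]
    if family == IGLESIAS_CHIRIFE:
        return params["A"] + params["B"] * aw / (1.0 - aw)
    if family == LINEAR:
        return (aw - params["a"]) / params["b"]
    raise DomainError(f"unknown isotherm family {family!r}")


def isotherm_moisture(fit: IsothermFit, aw):
    """Equilibrium dry-basis moisture at water activity ``aw``.

    Scalar in, scalar out; array in, array out.  For the GAB family, values
    above the model's validity range (aw > 0.94) trigger a warning and values
    at or beyond the pole ``aw = 1/k`` raise :class:`DomainError`.
    """
    aw_arr = np.asarray(aw, dtype=float)
    if np.any(aw_arr < 0) or np.any(aw_arr >= 1.0):
        raise DomainError(f"water activity must lie in [0, 1); got {aw!r}")
    if fit.family == GAB:
        pole = 1.0 / fit.params["k"]
        if np.any(aw_arr >= pole):
            raise DomainError(
                f"aw must stay below the GAB pole 1/k = {pole:.6g}"
            )
        if np.any(aw_arr > GAB_VALIDITY_AW):
            warnings.warn(
                f"aw above the GAB validity range (> {GAB_VALIDITY_AW}); "
                "extrapolating",
                stacklevel=2,
            )
    if fit.family == LINEAR and np.any(aw_arr < fit.params["a"]):
        raise DomainError(
            f"LINEAR isotherm is defined for aw >= intercept a = {fit.params['a']}"
        )
    out = _family_x(fit.family, fit.params, aw_arr)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# inverse evaluation aw(X)
# ---------------------------------------------------------------------------

def _gab_aw(x, xm, c, k):
    """Closed-form GAB inverse: quadratic in y = k*aw.

    X*(1-y)*(1-y+C*y) = Xm*C*y  expands to
    X*(C-1)*y**2 - (X*(C-2) - Xm*C)*y - X = 0.

    Roots come from the cancellation-free form q = -(a1 + sign(a1)*disc)/2
    with roots q/a2 and a0/q; of the candidates in (0, 1) the one whose
    forward evaluation reproduces ``x`` is kept (for C < 1 both roots are
    positive and naive branch selection picks the wrong one).
    """
    x = np.asarray(x, dtype=float)
    a2 = x * (c - 1.0)
    a1 = -(x * (c - 2.0) - xm * c)
    a0 = -x
    disc = np.sqrt(a1 * a1 - 4.0 * a2 * a0)
    sign = np.where(a1 >= 0, 1.0, -1.0)
    q = -(a1 + sign * disc) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(a2 != 0, q / np.where(a2 != 0, a2, 1.0), np.nan)
        r2 = np.where(q != 0, a0 / np.where(q != 0, q, 1.0), np.nan)
        r_lin = np.where(a1 != 0, -a0 / np.where(a1 != 0, a1, 1.0), 0.0)

    def fwd_err(y):
        ok = np.isfinite(y) & (y > 0) & (y < 1.0)
        ysafe = np.where(ok, y, 0.5)
        err = np.abs(_gab_x(ysafe / k, xm, c, k) - x)
        return np.where(ok, err, np.inf)

    linear_case = np.abs(a2) < 1e-300  # C == 1 degenerates to linear
    y = np.where(fwd_err(r1) <= fwd_err(r2), r1, r2)
    y = np.where(linear_case, r_lin, y)
    y = np.where(x == 0, 0.0, y)
    return y / k


def isotherm_aw(fit: IsothermFit, x):
    """Water activity at which the isotherm predicts moisture ``x``.

    Exact inverse of :func:`isotherm_moisture` (closed form for every
    family); round-trips to better than 1e-9 relative.  Raises
    :class:`RangeError` when ``x`` lies outside the attainable moisture range
    on the valid aw domain.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise DomainError("moisture must be >= 0")
    fam, p = fit.family, fit.params
    if fam == GAB:
        aw = _gab_aw(x_arr, p["Xm"], p["C"], p["k"])
    elif fam == HALSEY:
        with np.errstate(divide="ignore"):
            aw = np.where(x_arr > 0, np.exp(-p["A"] / np.maximum(x_arr, 1e-300) ** p["B"]), 0.0)
    elif fam == OSWIN:
        u = (x_arr / p["A"]) ** (1.0 / p["B"])
        aw = u / (1.0 + u)
    elif fam == IGLESIAS_CHIRIFE:
        if np.any(x_arr < p["A"]):
            raise RangeError(
                f"moisture below the IGLESIAS_CHIRIFE infimum A = {p['A']}"
            )
        u = (x_arr - p["A"]) / p["B"]
        aw = u / (1.0 + u)
    elif fam == LINEAR:
        aw = p["a"] + p["b"] * x_arr
        if np.any(aw >= 1.0):
            raise RangeError(
                "moisture above the LINEAR isotherm's supremum on aw < 1"
            )
    else:  # pragma: no cover - guarded in IsothermFit
        raise DomainError(f"unknown isotherm family {fam!r}")
    if np.any(~np.isfinite(aw)) or np.any(aw >= 1.0):
        raise RangeError("moisture above the isotherm's supremum on aw < 1")
    out = np.clip(aw, 0.0, None)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _as_arrays(points: Iterable[SorptionPoint] | tuple[Sequence, Sequence]):
    pts = list(points)
    if pts and isinstance(pts[0], SorptionPoint):
        temps = {p.temperature for p in pts}
        if len(temps) > 1:
            raise DomainError(
                f"all sorption points must share a temperature label; got {sorted(temps)}"
            )
        aw = np.array([p.water_activity for p in pts])
        x = np.array([p.moisture_db for p in pts])
        temp = pts[0].temperature if pts else 25.0
        return aw, x, temp
    raise DomainError("fit_isotherm expects a list of SorptionPoint")


def _starts(family, aw, x, n_starts, seed):
    """Seeded multi-start initial vectors (first one heuristic)."""
    rng = np.random.default_rng(seed)
    lo, hi = (np.array(v, dtype=float) for v in _BOUNDS[family])
    if family == GAB:
        first = [float(np.clip(np.min(x[x > 0], initial=0.05), 1e-4, 0.5)), 10.0, 0.8]
    elif family in (HALSEY, OSWIN):
        first = [max(float(np.median(x)), 1e-4), 1.0]
    elif family == IGLESIAS_CHIRIFE:
        first = [max(float(np.min(x)) * 0.9, 0.0), max(float(np.median(x)), 1e-4)]
    else:  # LINEAR handled analytically; never reaches here
        first = [0.0, 1.0]
    starts = [np.clip(first, lo + 1e-12, hi - 1e-12)]
    for _ in range(n_starts - 1):
        u = rng.uniform(size=lo.size)
        # log-uniform where the box spans decades, uniform otherwise
        span_log = (lo > 0) & (hi / np.maximum(lo, 1e-300) > 100)
        s = np.where(
            span_log,
            np.exp(np.log(np.maximum(lo, 1e-12)) + u * (np.log(hi) - np.log(np.maximum(lo, 1e-12)))),
            lo + u * (hi - lo),
        )
        starts.append(s)
    return starts


def fit_isotherm(
    points: Iterable[SorptionPoint],
    family: str = GAB,
    n_starts: int = 5,
    seed: int = 0,
) -> IsothermFit:
    """Fit an isotherm family to sorption points by bounded least squares.

    Moisture ``X`` is regressed on water activity (residuals in X).  Fitting
    uses ``scipy.optimize.least_squares`` with box constraints and
    ``n_starts`` seeded starting vectors to avoid local minima; the best
    converged solution is returned with its residual sum of squares.

    Raises
    ------
    InsufficientDataError
        If fewer than (number of parameters + 1) points are supplied.
    FitFailureError
        If no start converges; carries per-start diagnostics.
    """
    if family not in _PARAM_NAMES:
        raise DomainError(f"unknown isotherm family {family!r}")
    aw, x, temp = _as_arrays(points)
    n_par = len(_PARAM_NAMES[family])
    if len(x) < n_par + 1:
        raise InsufficientDataError(
            f"{family} fit needs at least {n_par + 1} points, got {len(x)}"
        )

    if family == LINEAR:
        # aw = a + b*X is linear; solve directly (residuals in X after inversion)
        coef = np.polyfit(aw, x, 1)  # x ~ c1*aw + c0
        c1, c0 = coef[0], coef[1]
        if c1 <= 0:
            raise FitFailureError(
                "LINEAR fit produced non-increasing isotherm",
                diagnostics={"coef": coef.tolist()},
            )
        params = {"a": -c0 / c1, "b": 1.0 / c1}
        rss = float(np.sum((np.polyval(coef, aw) - x) ** 2))
        return IsothermFit(LINEAR, params, temperature=temp, rss=rss, n_points=len(x))

    lo, hi = _BOUNDS[family]

    def resid(p):
        return _family_x(family, dict(zip(_PARAM_NAMES[family], p)), aw) - x

    best = None
    diagnostics = []
    for p0 in _starts(family, aw, x, n_starts, seed):
        try:
            res = least_squares(
                resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=2000,
            )
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            diagnostics.append({"start": list(p0), "error": str(exc)})
            continue
        diagnostics.append({"start": list(p0), "cost": res.cost, "status": res.status})
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError(
            f"{family} fit did not converge from any of {n_starts} starts",
            diagnostics={"starts": diagnostics},
        )
    params = dict(zip(_PARAM_NAMES[family], (float(v) for v in best.x)))
    return IsothermFit(
        family, params, temperature=temp, rss=float(2.0 * best.cost), n_points=len(x)
    )
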