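"""Powder quality indices and their classification rules.

Covers the standard bench indices for spray-dried powders: degree of caking
(sieve retention), Carr's compressibility index with its flowability
classes, rehydration ratio, a water-activity stability screen and the
FSSAI total-aerobic-bacteria limit for fruit powders (40,000 CFU/g).
Hygroscopicity and rehydration time are measured quantities with no derived
formula; they pass through validation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "FLOW_CLASSES",
    "QualityRecord",
    "degree_of_caking",
    "carr_index",
    "classify_flow",
    "rehydration_ratio",
    "classify_aw_stability",
    "tab_within_limit",
    "augment_quality",
]

#: Carr-index flow classes with closed-left breakpoints (%):
#: [0,15) very good, [15,20) good, [20,35) fair, [35,45) bad, >=45 very bad
FLOW_CLASSES = (
    (15.0, "very good"),
    (20.0, "good"),
    (35.0, "fair"),
    (45.0, "bad"),
    (float("inf"), "very bad"),
)

#: water-activity stability thresholds: <=0.60 stable, <=0.65 marginal
AW_STABLE_MAX = 0.60
AW_MARGINAL_MAX = 0.65

#: FSSAI total-aerobic-bacteria limit for fruit powders, CFU/g (inclusive)
TAB_LIMIT_CFU_PER_G = 40_000.0


def degree_of_caking(retained_g: float, sieved_g: float) -> float:
    """Percent of powder retained on the sieve after shaking: ``c/d*100``."""
    if sieved_g <= 0:
        raise DomainError("sieved mass d must be > 0")
    if not 0 <= retained_g <= sieved_g:
        raise DomainError("retained mass c must lie in [0, d]")
    return 100.0 * retained_g / sieved_g


def carr_index(rho_bulk: float, rho_tapped: float) -> float:
    """Carr's compressibility index ``(rho_t - rho_b)/rho_t * 100`` (%).

    Densities must be in the same units with ``rho_bulk <= rho_tapped``.
    """
    if rho_tapped <= 0:
        raise DomainError("tapped density must be > 0")
    if rho_bulk < 0 or rho_bulk > rho_tapped:
        raise DomainError("bulk density must lie in [0, tapped density]")
    return 100.0 * (rho_tapped - rho_bulk) / rho_tapped


def classify_flow(ci_pct: float) -> str:
    """Flowability class for a Carr index (%), closed-left boundaries."""
    if ci_pct < 0:
        raise DomainError("Carr index must be >= 0")
    for upper, label in FLOW_CLASSES:
        if ci_pct < upper:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def rehydration_ratio(w_rehydrated_g: float, w_dried_g: float) -> float:
    """Mass of rehydrated sample over mass of dried sample."""
    if w_dried_g <= 0:
        raise DomainError("dried mass must be > 0")
    if w_rehydrated_g < 0:
        raise DomainError("rehydrated mass must be >= 0")
    return w_rehydrated_g / w_dried_g


def classify_aw_stability(aw: float) -> str:
    """Stability screen on water activity.

    ``stable`` up to 0.60, ``marginal`` up to 0.65, ``unstable`` above --
    the two-threshold scheme spans the usual microbial-stability cutoffs
    quoted for fruit powders.
    """
    if not 0 <= aw < 1:
        raise DomainError("water activity must lie in [0, 1)")
    if aw <= AW_STABLE_MAX:
        return "stable"
    if aw <= AW_MARGINAL_MAX:
        return "marginal"
    return "unstable"


def tab_within_limit(count_cfu_per_g: float) -> bool:
    """True iff the total aerobic count is within the 40,000 CFU/g limit."""
    if count_cfu_per_g < 0:
        raise DomainError("plate count must be >= 0")
    return count_cfu_per_g <= TAB_LIMIT_CFU_PER_G


@dataclass
class QualityRecord:
    """One sample's quality indices with derived classifications."""

    degree_of_caking: float | None = None
    carr_index: float | None = None
    hygroscopicity: float | None = None
    rehydration_time: float | None = None
    rehydration_ratio: float | None = None
    aw: float | None = None
    tab_count: float | None = None

    def __post_init__(self):
        if self.degree_of_caking is not None and not 0 <= self.degree_of_caking <= 100:
            raise DomainError("degree_of_caking must lie in [0, 100]")
        if self.carr_index is not None and not 0 <= self.carr_index < 100:
            raise DomainError("carr_index must lie in [0, 100)")
        if self.rehydration_ratio is not None and self.rehydration_ratio < 0:
            raise DomainError("rehydration_ratio must be >= 0")

    @property
    def flow_class(self) -> str | None:
        return None if self.carr_index is None else classify_flow(self.carr_index)

    @property
    def aw_stability(self) -> str | None:
        return None if self.aw is None else classify_aw_stability(self.aw)

    @property
    def tab_safe(self) -> bool | None:
        return None if self.tab_count is None else tab_within_limit(self.tab_count)


def augment_quality(table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise classification of a long-format storage table.

    Adds ``flow_class`` (from ``carr_index_pct``), ``aw_stability`` (from
    ``aw``) and ``tab_safe`` (from ``tpc_cfu_per_g``) columns where the
    source columns exist; missing values stay missing.
    """
    out = table.copy()
    if "carr_index_pct" in out:
        out["flow_class"] = [
            classify_flow(v) if np.isfinite(v) else None for v in out["carr_index_pct"]
        ]
    if "aw" in out:
        out["aw_stability"] = [
            classify_aw_stability(v) if np.isfinite(v) else None for v in out["aw"]
        ]
    if "tpc_cfu_per_g" in out:
        out["tab_safe"] = [
            tab_within_limit(v) if np.isfinite(v) else None
            for v in out["tpc_cfu_per_g"]
        ]
    return out
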