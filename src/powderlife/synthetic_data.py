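"""Seeded synthetic storage experiments with the structure of the bundled trial.

The generator emulates a moisture-uptake storage study: a latent dry-basis
moisture trajectory follows the package moisture balance under each series'
"true" isotherm; observed moisture carries multiplicative Gaussian noise,
observed water activity additive Gaussian noise (matching the roughly
constant SDs that storage tables report); and the bench attributes (caking,
Carr index, hygroscopicity, rehydration, colour, plate count) drift
linearly with the latent moisture gain from their day-0 baselines, total
plate count on the log10 scale floored at its baseline.  All draws descend
from one seed, keyed per series so output is independent of series order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DomainError, FitFailureError
from .isotherms import (
    GAB,
    IsothermFit,
    SorptionPoint,
    dry_to_wet_basis,
    fit_isotherm,
    isotherm_aw,
    wet_basis_to_dry,
)
from .moisture_transfer import EnvironmentSpec, PackageSpec, PowderSpec, integrate_uptake
from .shelflife import experimental_shelf_life, predict_shelf_life

__all__ = [
    "NoiseSpec",
    "SyntheticConfig",
    "generate_storage_experiment",
    "recovery_experiment",
]

#: attributes drifting linearly with latent moisture gain (log10 scale for TPC)
_LINEAR_ATTRS = (
    "caking_pct",
    "carr_index_pct",
    "hygroscopicity",
    "prt_min",
    "rr",
    "L",
    "a",
    "b",
)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise levels.

    ``moisture_cv``: multiplicative CV on wet-basis moisture (the trial's
    printed moisture SDs of ~0.03% absolute on ~6% readings give ~0.005);
    ``aw_sd``: additive SD on water activity (printed SDs cluster at 0.03);
    ``attribute_cv``: multiplicative CV on the bench attributes (printed
    SD/mean ratios run 0.03-0.15; 0.08 is representative).
    """

    moisture_cv: float = 0.005
    aw_sd: float = 0.03
    attribute_cv: float = 0.08

    def __post_init__(self):
        if min(self.moisture_cv, self.aw_sd, self.attribute_cv) < 0:
            raise DomainError("noise levels must be >= 0")


@dataclass
class SyntheticConfig:
    """Design of a synthetic storage experiment.

    Unset fields default to the bundled trial's conditions: its per-series
    GAB fits as the true isotherms, the printed package/powder constants
    with the calibrated critical moisture, the two storage environments and
    the day-0 attribute baselines with slopes estimated from the trial.
    """

    treatments: tuple[str, ...] = ("control", "TCP", "SiO2")
    conditions: tuple[str, ...] = ("ambient", "accelerated")
    sampling_days: tuple[float, ...] = (0, 30, 60, 90, 120, 140, 160, 180)
    isotherms: dict[tuple[str, str], IsothermFit] | None = None
    pkg: PackageSpec | None = None
    powder: PowderSpec | None = None
    environments: dict[str, EnvironmentSpec] | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    baselines: dict[str, float] | None = None
    slopes: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        days = np.asarray(self.sampling_days, dtype=float)
        if len(days) < 2 or days[0] != 0 or np.any(np.diff(days) <= 0):
            raise DomainError("sampling_days must be strictly increasing from 0")
        if not self.treatments or not self.conditions:
            raise DomainError("need at least one treatment and one condition")

    def resolved(self) -> "SyntheticConfig":
        """Fill unset fields from the bundled trial (see class docstring)."""
        from . import datasets  # deferred: datasets pulls in the fixture

        out = self
        ref = None
        if out.isotherms is None or out.powder is None:
            ref = datasets.reference_analysis()
        if out.isotherms is None:
            iso = {
                key: ref["fits"][key]
                for key in ref["fits"]
                if key[0] in out.treatments and key[1] in out.conditions
            }
            out = replace(out, isotherms=iso)
        if out.pkg is None:
            c = datasets.study_constants()["package"]
            out = replace(out, pkg=PackageSpec(permeability_K=c["K"], area_Ap=c["Ap"]))
        if out.powder is None:
            c = datasets.study_constants()["powder"]
            out = replace(
                out,
                powder=PowderSpec(
                    dry_mass_Ws=c["Ws"],
                    X_initial=float(ref["rescale"].data_lo),
                    X_critical=float(ref["critical_moisture_db"]),
                ),
            )
        if out.environments is None:
            envs = datasets.study_constants()["environment"]
            out = replace(
                out,
                environments={
                    k: EnvironmentSpec(e["T"], e["Rh"], e["pstar"])
                    for k, e in envs.items()
                },
            )
        if out.baselines is None:
            out = replace(out, baselines=_trial_baselines())
        if out.slopes is None:
            out = replace(out, slopes=_trial_slopes())
        missing = [
            (t, c)
            for t in out.treatments
            for c in out.conditions
            if (t, c) not in out.isotherms
        ]
        if missing:
            raise DomainError(f"no true isotherm for series {missing}")
        return out


def _trial_baselines() -> dict[str, float]:
    from . import datasets

    series = next(iter(datasets.load_storage_trial().values()))
    row = series.data.iloc[0]
    out = {a: float(row[a]) for a in _LINEAR_ATTRS}
    out["tpc_cfu_per_g"] = float(row["tpc_cfu_per_g"])
    return out


def _trial_slopes() -> dict[str, float]:
    """Least-squares slope of each attribute on latent moisture gain,
    pooled over the bundled trial's six series."""
    from . import datasets

    series_map = datasets.load_storage_trial()
    dx, cols = [], {a: [] for a in (*_LINEAR_ATTRS, "tpc_cfu_per_g")}
    for s in series_map.values():
        x = s.moisture_db()
        dx.extend(x - x[0])
        for a in cols:
            cols[a].extend(s.data[a].to_numpy(dtype=float))
    dx = np.asarray(dx)
    slopes = {}
    for a, v in cols.items():
        y = np.log10(v) if a == "tpc_cfu_per_g" else np.asarray(v)
        slopes[a] = float(np.polyfit(dx, y, 1)[0])
    return slopes


_CANONICAL_TREATMENTS = {"control": 0, "TCP": 1, "SiO2": 2}
_CANONICAL_CONDITIONS = {"ambient": 0, "accelerated": 1}


def _series_rng(cfg: SyntheticConfig, treatment: str, condition: str):
    """Per-series generator keyed by stable name hashes, so output does not
    depend on the order in which series are listed or generated."""
    import zlib

    ti = _CANONICAL_TREATMENTS.get(treatment, 10 + zlib.crc32(treatment.encode()))
    ci = _CANONICAL_CONDITIONS.get(condition, 10 + zlib.crc32(condition.encode()))
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(ti), int(ci)])
    )


def generate_storage_experiment(cfg: SyntheticConfig):
    """Generate one synthetic storage experiment.

    Returns ``(table, truth)``: a long-format DataFrame in the storage-table
    schema and a JSON-serializable ground-truth dict carrying, per series,
    the true isotherm, the latent moisture at the sampling days and the true
    crossing time of the powder's critical moisture.  The same config and
    seed reproduce the output bit for bit.
    """
    cfg = cfg.resolved()
    days = np.asarray(cfg.sampling_days, dtype=float)
    rows, truth = [], {"seed": cfg.seed, "series": {}}
    for treatment in cfg.treatments:
        for condition in cfg.conditions:
            fit = cfg.isotherms[(treatment, condition)]
            env = cfg.environments[condition]
            rng = _series_rng(cfg, treatment, condition)
            traj = integrate_uptake(
                fit, cfg.pkg, env, cfg.powder,
                horizon=float(days[-1]), t_eval=days,
            )
            x = traj.moisture_db
            aw_true = traj.water_activity
            nz = cfg.noise
            m_obs = dry_to_wet_basis(x) * (1 + nz.moisture_cv * rng.standard_normal(len(x)))
            aw_obs = np.clip(aw_true + nz.aw_sd * rng.standard_normal(len(x)), 0.0, 0.999999)
            rec = {
                "treatment": treatment, "condition": condition,
            }
            attr_obs = {}
            gain = x - cfg.powder.X_initial
            for a in _LINEAR_ATTRS:
                base = cfg.baselines[a] + cfg.slopes[a] * gain
                attr_obs[a] = base * (1 + nz.attribute_cv * rng.standard_normal(len(x)))
            log_tpc = (
                np.log10(cfg.baselines["tpc_cfu_per_g"])
                + cfg.slopes["tpc_cfu_per_g"] * gain
                + nz.attribute_cv * rng.standard_normal(len(x))
            )
            attr_obs["tpc_cfu_per_g"] = np.maximum(
                10.0 ** log_tpc, cfg.baselines["tpc_cfu_per_g"]
            )
            for i, day in enumerate(days):
                row = dict(rec, day=float(day),
                           moisture_pct_wb=float(m_obs[i]), aw=float(aw_obs[i]))
                row.update({a: float(attr_obs[a][i]) for a in attr_obs})
                rows.append(row)
            res = predict_shelf_life(fit, cfg.pkg, env, cfg.powder,
                                     treatment=treatment, condition=condition)
            truth["series"][f"{treatment}/{condition}"] = {
                "isotherm": fit.to_dict(),
                "latent_moisture_db": [float(v) for v in x],
                "true_crossing_days": float(res.theta_days) if res.reached else None,
            }
    return pd.DataFrame(rows), truth


def recovery_experiment(cfg: SyntheticConfig, n_replicates: int, seed: int | None = None):
    """Generate -> fit -> predict recovery study.

    For each replicate: generate a synthetic experiment, refit a GAB
    isotherm per series from its noisy (aw, moisture) pairs, predict the
    crossing time of the critical moisture with the refitted isotherm, and
    interpolate the noisy series' own crossing.  Reports per-series GAB
    parameter errors and crossing-time errors; fit failures and non-finite
    crossings are counted, not fatal.
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    cfg = cfg.resolved()
    base_seed = cfg.seed if seed is None else int(seed)
    records = []
    n_fit_failures = 0
    for rep in range(n_replicates):
        rep_cfg = replace(cfg, seed=(base_seed * 100003 + rep) % (2**31))
        table, truth = generate_storage_experiment(rep_cfg)
        for (treatment, condition), g in table.groupby(["treatment", "condition"]):
            key = f"{treatment}/{condition}"
            true = truth["series"][key]
            env = cfg.environments[condition]
            pts = [
                SorptionPoint(
                    moisture_db=float(wet_basis_to_dry(m)),
                    water_activity=float(a),
                    temperature=env.temperature_T,
                )
                for m, a in zip(g["moisture_pct_wb"], g["aw"])
            ]
            try:
                fit = fit_isotherm(pts, GAB, seed=rep_cfg.seed)
            except FitFailureError:
                n_fit_failures += 1
                continue
            pred = predict_shelf_life(fit, cfg.pkg, env, cfg.powder)
            days = g["day"].to_numpy(dtype=float)
            x_obs = wet_basis_to_dry(g["moisture_pct_wb"].to_numpy(dtype=float))
            expr = experimental_shelf_life((days, x_obs), cfg.powder.X_critical)
            rec = {"replicate": rep, "series": key,
                   "true_crossing": true["true_crossing_days"],
                   "predicted_crossing": pred.theta_days if pred.reached else np.nan,
                   "experimental_crossing": expr.theta_days if expr.reached else np.nan}
            true_iso = true["isotherm"]
            if true_iso["family"] == GAB:
                for name in ("Xm", "C", "k"):
                    tv = true_iso["params"][name]
                    rec[f"rel_err_{name}"] = (fit.params[name] - tv) / tv
            records.append(rec)
    df = pd.DataFrame(records)
    finite = df.dropna(subset=["predicted_crossing"]) if len(df) else df
    finite = finite[finite["true_crossing"].notna()] if len(finite) else finite
    summary = {
        "n_replicates": n_replicates,
        "n_fit_failures": n_fit_failures,
        "n_finite_recoveries": int(len(finite)),
    }
    if len(finite):
        err = finite["predicted_crossing"] - finite["true_crossing"]
        summary.update(
            crossing_bias_days=float(err.mean()),
            crossing_rmse_days=float(np.sqrt((err**2).mean())),
            crossing_median_abs_rel=float(
                (err.abs() / finite["true_crossing"]).median()
            ),
        )
        for name in ("Xm", "C", "k"):
            col = f"rel_err_{name}"
            if col in finite:
                summary[f"{name}_bias_rel"] = float(finite[col].mean())
                summary[f"{name}_rmse_rel"] = float(np.sqrt((finite[col] ** 2).mean()))
    return {"records": df, "summary": summary}
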