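"""Readers, writers and the pipeline orchestrator.

Storage experiments travel as long-format CSV with one row per
treatment x condition x sampling day and one column per measured attribute
(moisture as wet-basis percent, water activity, caking, Carr index,
hygroscopicity, rehydration time/ratio, CIELAB colour, plate count), with
optional per-cell standard deviations in ``<column>_sd`` companions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, SchemaError
from .isotherms import SorptionPoint, wet_basis_to_dry
from .moisture_transfer import EnvironmentSpec, PackageSpec, PowderSpec

__all__ = [
    "MANDATORY_COLUMNS",
    "ATTRIBUTE_COLUMNS",
    "StorageSeries",
    "read_storage_csv",
    "write_storage_csv",
    "series_to_frame",
    "load_config",
    "build_specs",
    "run_pipeline",
]

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("treatment", "condition", "day", "moisture_pct_wb", "aw")
ATTRIBUTE_COLUMNS = (
    "moisture_pct_wb",
    "aw",
    "caking_pct",
    "carr_index_pct",
    "hygroscopicity",
    "prt_min",
    "rr",
    "L",
    "a",
    "b",
    "tpc_cfu_per_g",
)
_KNOWN_COLUMNS = set(MANDATORY_COLUMNS) | set(ATTRIBUTE_COLUMNS) | {
    f"{c}_sd" for c in ATTRIBUTE_COLUMNS
}


@dataclass
class StorageSeries:
    """One treatment x condition storage time series.

    ``data`` is indexed by sampling day and holds the attribute columns
    (and optional ``_sd`` companions) present in the source table.
    """

    treatment: str
    condition: str
    data: pd.DataFrame

    def __post_init__(self):
        days = self.data.index.to_numpy(dtype=float)
        if len(days) != len(set(days)):
            raise SchemaError(
                f"{self.treatment}/{self.condition}: duplicate sampling days"
            )
        if np.any(np.diff(days) <= 0):
            self.data = self.data.sort_index()

    @property
    def days(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    def moisture_db(self) -> np.ndarray:
        """Dry-basis moisture (kg/kg) converted from the wet-basis column."""
        return wet_basis_to_dry(self.data["moisture_pct_wb"].to_numpy(dtype=float))

    @property
    def aw(self) -> np.ndarray:
        return self.data["aw"].to_numpy(dtype=float)

    def sorption_points(self, temperature: float) -> list[SorptionPoint]:
        """The series' (moisture, aw) pairs as sorption points."""
        return [
            SorptionPoint(moisture_db=float(x), water_activity=float(a),
                          temperature=temperature)
            for x, a in zip(self.moisture_db(), self.aw)
        ]


def _validate_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    bad = []
    for col in df.columns:
        if col in ("treatment", "condition"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        for row in df.index[coerced.isna() & df[col].notna()]:
            bad.append((int(row) + 2, col))  # +2: header line + 1-based
        df[col] = coerced
    if bad:
        coords = ", ".join(f"line {r} column {c!r}" for r, c in bad[:20])
        raise SchemaError(f"malformed numeric cells in {path}: {coords}")
    return df


def read_storage_csv(path) -> dict[tuple[str, str], StorageSeries]:
    """Read a long-format storage table into per-series objects.

    Returns a dict keyed by ``(treatment, condition)``.  Mandatory columns
    are ``treatment, condition, day, moisture_pct_wb, aw``; unknown columns
    are kept but warned about; rows are sorted by day (with a warning when
    they arrive out of order).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"treatment": str, "condition": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty or has no header") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in _KNOWN_COLUMNS]
    if unknown:
        warnings.warn(f"{path.name}: ignoring unknown columns {unknown}", stacklevel=2)
    df = _validate_numeric(df, path.name)
    if np.any(df["moisture_pct_wb"] < 0) or np.any(df["moisture_pct_wb"] >= 100):
        raise SchemaError(f"{path.name}: moisture_pct_wb must lie in [0, 100)")
    if np.any(df["aw"] < 0) or np.any(df["aw"] >= 1):
        raise SchemaError(f"{path.name}: aw must lie in [0, 1)")

    out: dict[tuple[str, str], StorageSeries] = {}
    for (treatment, condition), g in df.groupby(["treatment", "condition"], sort=False):
        g = g.drop(columns=["treatment", "condition"])
        if np.any(np.diff(g["day"].to_numpy(dtype=float)) <= 0):
            warnings.warn(
                f"{path.name}: days out of order for {treatment}/{condition}; sorting",
                stacklevel=2,
            )
            g = g.sort_values("day")
        out[(treatment, condition)] = StorageSeries(
            treatment=treatment,
            condition=condition,
            data=g.set_index("day"),
        )
    return out


def series_to_frame(series_map: dict[tuple[str, str], StorageSeries]) -> pd.DataFrame:
    """Concatenate per-series objects back into one long-format table."""
    frames = []
    for (treatment, condition), s in series_map.items():
        g = s.data.reset_index()
        g.insert(0, "condition", condition)
        g.insert(0, "treatment", treatment)
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def write_storage_csv(series_map: dict[tuple[str, str], StorageSeries], path) -> None:
    """Write per-series objects as a long-format CSV (round-trips exactly)."""
    series_to_frame(series_map).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path} must contain a mapping at top level")
    return cfg


def build_specs(cfg: dict) -> tuple[PackageSpec, dict[str, EnvironmentSpec], PowderSpec]:
    """Build package/environment/powder specs from a configuration mapping.

    Expected blocks::

        package:     {K: ..., Ap: ...}            # or width/height/faces
        environment: {ambient: {T: ..., Rh: ..., pstar: ...}, ...}
        powder:      {Ws: ..., Xi: ..., Xc: ...}
    """
    try:
        p = cfg["package"]
        pkg = PackageSpec(
            permeability_K=float(p["K"]),
            area_Ap=float(p["Ap"]) if "Ap" in p else None,
            width=float(p["width"]) if "width" in p else None,
            height=float(p["height"]) if "height" in p else None,
            faces=int(p.get("faces", 2)),
        )
        envs = {}
        env_block = cfg["environment"]
        if "T" in env_block:  # single unnamed environment
            env_block = {"default": env_block}
        for name, e in env_block.items():
            envs[name] = EnvironmentSpec(
                temperature_T=float(e["T"]),
                rel_humidity_Rh=float(e["Rh"]),
                sat_pressure_pstar=float(e["pstar"]) if "pstar" in e else None,
            )
        w = cfg["powder"]
        powder = PowderSpec(
            dry_mass_Ws=float(w["Ws"]),
            X_initial=float(w["Xi"]),
            X_critical=float(w["Xc"]),
        )
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return pkg, envs, powder


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, out_dir, seed: int = 0) -> dict:
    """Run the full analysis: fit isotherms, predict and extract shelf
    lives, classify quality, and compare predictions with observations.

    ``cfg`` must name an ``input_csv`` or set ``simulate: true``; outputs
    (isotherm JSON, trajectory CSVs, shelf-life JSON, quality CSV,
    comparison metrics, summary) are written under ``out_dir``.  Returns the
    summary as a dict.
    """
    from . import shelflife as sl  # local import avoids a cycle
    from .isotherms import GAB, fit_isotherm
    from .moisture_transfer import integrate_uptake
    from .quality_indices import augment_quality

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pkg, envs, powder = build_specs(cfg)

    if cfg.get("simulate"):
        from .synthetic_data import SyntheticConfig, generate_storage_experiment

        sim = cfg["simulate"]
        sim_kwargs = {"seed": seed}
        if isinstance(sim, dict):
            for k in ("treatments", "conditions", "sampling_days"):
                if k in sim:
                    sim_kwargs[k] = tuple(sim[k])
        sim_cfg = SyntheticConfig(**sim_kwargs)
        table, truth = generate_storage_experiment(sim_cfg)
        sim_path = out_dir / "simulated_storage.csv"
        table.to_csv(sim_path, index=False)
        with open(out_dir / "simulated_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
        series_map = read_storage_csv(sim_path)
        sim_xc_db = sim_cfg.resolved().powder.X_critical
    else:
        sim_xc_db = None
        if "input_csv" not in cfg:
            raise ConfigError("config must name input_csv or set simulate: true")
        series_map = read_storage_csv(cfg["input_csv"])

    # per-series isotherm fits
    fits, fit_json = {}, {}
    for key, series in series_map.items():
        env = envs.get(series.condition) or envs.get("default")
        if env is None:
            raise ConfigError(f"no environment block for condition {series.condition!r}")
        fit = fit_isotherm(series.sorption_points(env.temperature_T), GAB, seed=seed)
        fit.series = f"{key[0]}/{key[1]}"
        fits[key] = fit
        fit_json[f"{key[0]}/{key[1]}"] = fit.to_dict()
    with open(out_dir / "isotherms.json", "w") as fh:
        json.dump(fit_json, fh, indent=2)

    # critical moisture on the data scale
    crit = cfg.get("critical", {})
    if "Xc_db" in crit:
        xc_db = float(crit["Xc_db"])
    elif "stated_days" in crit:
        stated = {tuple(k.split("/")): float(v) for k, v in crit["stated_days"].items()}
        xc_db = sl.calibrate_critical_moisture(series_map, stated)
    elif sim_xc_db is not None:
        xc_db = sim_xc_db  # the simulation's own ground-truth critical moisture
    else:
        xc_db = powder.X_critical
    day0 = max(float(s.moisture_db()[0]) for s in series_map.values())
    if xc_db <= day0:
        raise ConfigError(
            f"critical moisture {xc_db:.4g} is not above the series' initial "
            f"dry-basis moisture {day0:.4g}; give critical.Xc_db or "
            "critical.stated_days on the data scale"
        )
    log.info("critical dry-basis moisture: %.6g", xc_db)

    results = {}
    comparisons = {}
    pooled_pred, pooled_obs = [], []
    for key, series in series_map.items():
        env = envs.get(series.condition) or envs.get("default")
        x0 = float(series.moisture_db()[0])
        pw = PowderSpec(powder.dry_mass_Ws, x0, xc_db)
        pred = sl.predict_shelf_life(fits[key], pkg, env, pw,
                                     treatment=key[0], condition=key[1])
        expr = sl.experimental_shelf_life(series, xc_db,
                                          treatment=key[0], condition=key[1])
        horizon = max(float(series.days[-1]), 1.0)
        traj = integrate_uptake(fits[key], pkg, env, pw, horizon=horizon)
        pd.DataFrame({
            "theta_days": traj.times,
            "X_db": traj.moisture_db,
            "aw": traj.water_activity,
        }).to_csv(out_dir / f"trajectory_{key[0]}_{key[1]}.csv", index=False)
        comp = sl.compare_trajectories(traj, series)
        pooled_pred.extend(comp["pairs"]["predicted"])
        pooled_obs.extend(comp["pairs"]["observed"])
        results[f"{key[0]}/{key[1]}"] = {
            "predicted": pred.to_dict(),
            "experimental": expr.to_dict(),
        }
        comparisons[f"{key[0]}/{key[1]}"] = {
            "pearson_r": comp["pearson_r"], "rmse": comp["rmse"], "n": comp["n"],
        }

    pooled_r = float(np.corrcoef(pooled_pred, pooled_obs)[0, 1]) if len(pooled_pred) > 2 else None
    with open(out_dir / "shelf_life.json", "w") as fh:
        json.dump(results, fh, indent=2)
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump({"per_series": comparisons, "pooled_pearson_r": pooled_r}, fh, indent=2)

    quality = augment_quality(series_to_frame(series_map))
    quality.to_csv(out_dir / "quality.csv", index=False)

    summary = {
        "seed": seed,
        "n_series": len(series_map),
        "critical_moisture_db": xc_db,
        "shelf_life_days": {
            k: {
                "predicted": v["predicted"]["theta_days"],
                "experimental": v["experimental"]["theta_days"],
            }
            for k, v in results.items()
        },
        "pooled_pearson_r": pooled_r,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    lines = [
        "powderlife pipeline summary",
        f"  series: {len(series_map)}, critical moisture (dry basis): {xc_db:.5f}",
    ]
    for k, v in summary["shelf_life_days"].items():
        p, e = v["predicted"], v["experimental"]
        lines.append(
            f"  {k:24s} predicted "
            f"{'never' if p is None else format(p, '7.1f')} d, "
            f"experimental {'never' if e is None else format(e, '7.1f')} d"
        )
    if pooled_r is not None:
        lines.append(f"  pooled predicted-vs-observed Pearson r: {pooled_r:.3f}")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    for line in lines:
        log.info("%s", line)
    return summary
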