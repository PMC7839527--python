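"""File dialects, run configuration and reproducibility manifests.

Plain comma-delimited text for tables, JSON for summaries and manifests,
ISO-8601 dates.  Every writer emits a manifest (inputs, seed, versions,
checksums) so any output can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "load_config",
    "read_inventory",
    "write_inventory",
    "read_met",
    "write_met",
    "read_trait_observations",
    "write_results",
    "monthly_precip",
]

INVENTORY_COLUMNS = {
    "patch_id": str,
    "stem_id": str,
    "growth_form": str,
    "dbh_cm": float,
    "wood_density_g_cm3": float,
    "density_multiplier": float,
}
MET_COLUMNS = {
    "date": str,
    "precip_mm": float,
    "par_umol_m2_s": float,
    "tair_C": float,
    "rh_frac": float,
}
TRAIT_COLUMNS = {
    "trait": str, "mean": float, "se": float, "n": float,
    "study_id": str, "site_id": str,
}


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run (strict schema)."""

    site: str = "bci"
    years: int = 5
    seed: int = 0
    ensemble_n: int = 250
    sensitivity_output: str = "liana_gpp"
    dry_season_only: bool = False
    young_patches_only: bool = False
    no_lianas: bool = False
    parameter_set: str = "posterior"  # prior | posterior | path to a file
    inventory_path: str | None = None
    met_path: str | None = None
    n_patches: int | None = None
    # simulator physical constants (defaults mirror SimulatorConfig)
    k_ext: float = 0.5
    h_offset: float = 0.5
    dbh_threshold: float = 3.0
    interception_frac: float = 0.10
    soil_evap_max: float = 2.0
    c_xylem: float = 5.0
    c_soilroot: float = 0.01
    ca_ppm: float = 370.0
    substeps_per_day: int = 24
    seed_defaulted: bool = field(default=False, repr=False)

    def simulator_config(self):
        from .simulator import SimulatorConfig

        return SimulatorConfig(
            k_ext=self.k_ext, h_offset=self.h_offset,
            dbh_threshold=self.dbh_threshold,
            interception_frac=self.interception_frac,
            soil_evap_max=self.soil_evap_max, c_xylem=self.c_xylem,
            c_soilroot=self.c_soilroot, ca_ppm=self.ca_ppm,
            substeps_per_day=self.substeps_per_day,
        )

    def to_dict(self):
        d = dataclasses.asdict(self)
        d.pop("seed_defaulted", None)
        return d


def load_config(path) -> RunConfig:
    """Strict YAML config parsing: unknown keys are rejected; a missing
    seed falls back to the default and is flagged for the manifest."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"seed_defaulted"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.seed_defaulted = "seed" not in raw
    return cfg


def _read_table(path, schema, required, name):
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise ValueError(f"{path}: not valid UTF-8 ({exc})") from None
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: {name} missing columns {sorted(missing)}")
    for col, typ in schema.items():
        if col not in df.columns:
            continue
        if typ is float:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise ValueError(
                    f"{path}: column {col!r} has a non-numeric value at line {row}"
                )
            df[col] = coerced
    for col in required:
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 2
            raise ValueError(f"{path}: required field {col!r} is missing at line {row}")
    return df


def read_inventory(path) -> pd.DataFrame:
    required = ["patch_id", "stem_id", "growth_form", "dbh_cm"]
    df = _read_table(path, INVENTORY_COLUMNS, required, "inventory")
    bad = ~df["growth_form"].isin(["tree", "liana"])
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: growth_form must be tree|liana (line {row})")
    if (df["dbh_cm"] <= 0).any():
        row = int((df["dbh_cm"] <= 0).idxmax()) + 2
        raise ValueError(f"{path}: dbh_cm must be > 0 (line {row})")
    if "density_multiplier" not in df.columns:
        df["density_multiplier"] = 1.0
    return df


def write_inventory(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_met(path) -> pd.DataFrame:
    df = _read_table(path, MET_COLUMNS, list(MET_COLUMNS), "met")
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: dates must be ISO-8601 YYYY-MM-DD ({exc})") from None
    if not (df["rh_frac"].between(0, 1)).all():
        row = int((~df["rh_frac"].between(0, 1)).idxmax()) + 2
        raise ValueError(f"{path}: rh_frac outside [0, 1] at line {row}")
    if (df["precip_mm"] < 0).any():
        row = int((df["precip_mm"] < 0).idxmax()) + 2
        raise ValueError(f"{path}: negative precipitation at line {row}")
    return df


def write_met(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_trait_observations(path) -> pd.DataFrame:
    return _read_table(path, TRAIT_COLUMNS, ["trait", "mean", "study_id"], "traits")


def monthly_precip(met: pd.DataFrame) -> pd.Series:
    met = met.copy()
    met["date"] = pd.to_datetime(met["date"])
    return met.groupby(met["date"].dt.to_period("M"))["precip_mm"].sum()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_results(outdir, objects: dict, config: RunConfig | None = None,
                  inputs: dict | None = None) -> Path:
    """Write result tables/objects plus a manifest enabling exact re-runs.

    ``objects`` maps file stems to DataFrames (written as CSV) or
    JSON-serializable objects (written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for stem, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{stem}.csv"
            obj.to_csv(p, index=False)
        else:
            p = outdir / f"{stem}.json"
            p.write_text(json.dumps(obj, indent=2, default=_json_default))
        written[p.name] = _sha256(p)
    manifest = {
        "outputs": written,
        "inputs": {k: (_sha256(v) if Path(str(v)).is_file() else str(v))
                   for k, v in (inputs or {}).items()},
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if config is not None:
        manifest["config"] = config.to_dict()
        manifest["seed_defaulted"] = config.seed_defaulted
        (outdir / "config.resolved.yaml").write_text(yaml.safe_dump(config.to_dict()))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
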