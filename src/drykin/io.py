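"""CSV / YAML input and output for drying runs and result tables.

A run on disk is a two-column CSV (``time_min, weight_kg``) plus a YAML
sidecar with the run metadata; alternatively a long-format CSV carries
several runs with a ``run_id`` column and per-row metadata columns.
Moisture content crosses the I/O boundary as percent dry basis and is
stored internally as a fraction.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .curves import DryingRun

__all__ = [
    "read_run_csv",
    "write_run_csv",
    "read_runs_long_csv",
    "write_runs_long_csv",
    "load_runs",
]

_META_KEYS = (
    "run_id",
    "temperature_C",
    "thickness_mm",
    "air_velocity_m_s",
    "initial_load_kg",
    "initial_moisture_db_percent",
)


def _run_from_parts(meta: dict, times, weights) -> DryingRun:
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValueError(f"run metadata missing keys: {', '.join(missing)}")
    m0 = float(meta["initial_moisture_db_percent"]) / 100.0
    load = float(meta["initial_load_kg"])
    dry_mass = float(meta.get("dry_mass_kg", load / (1.0 + m0)))
    return DryingRun(
        run_id=str(meta["run_id"]),
        temperature=float(meta["temperature_C"]),
        thickness=float(meta["thickness_mm"]) / 1000.0,
        air_velocity=float(meta["air_velocity_m_s"]),
        initial_load=load,
        dry_mass=dry_mass,
        times=times,
        weights=weights,
        initial_moisture_db=m0,
    )


def _meta_dict(run: DryingRun) -> dict:
    return {
        "run_id": run.run_id,
        "temperature_C": run.temperature,
        "thickness_mm": run.thickness * 1000.0,
        "air_velocity_m_s": run.air_velocity,
        "initial_load_kg": run.initial_load,
        "dry_mass_kg": run.dry_mass,
        "initial_moisture_db_percent": run.initial_moisture_db * 100.0,
    }


def read_run_csv(csv_path: str | Path, sidecar_path: str | Path | None = None) -> DryingRun:
    """Read one run from ``time_min,weight_kg`` CSV plus a YAML sidecar.

    The sidecar defaults to the CSV path with a ``.yaml`` suffix.
    """
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    df = pd.read_csv(csv_path)
    for col in ("time_min", "weight_kg"):
        if col not in df.columns:
            raise ValueError(f"{csv_path}: missing column {col!r}")
    return _run_from_parts(meta, df["time_min"].to_numpy(), df["weight_kg"].to_numpy())


def write_run_csv(run: DryingRun, csv_path: str | Path) -> None:
    """Write one run as CSV plus YAML sidecar (same stem)."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_min": run.times, "weight_kg": run.weights}).to_csv(
        csv_path, index=False
    )
    csv_path.with_suffix(".yaml").write_text(
        yaml.safe_dump(_meta_dict(run), sort_keys=False)
    )


def read_runs_long_csv(path: str | Path) -> list[DryingRun]:
    """Read several runs from a long-format CSV keyed by ``run_id``."""
    df = pd.read_csv(path)
    needed = set(_META_KEYS) | {"time_min", "weight_kg"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    runs = []
    for run_id, grp in df.groupby("run_id", sort=False):
        grp = grp.sort_values("time_min")
        meta = {k: grp.iloc[0][k] for k in _META_KEYS}
        if "dry_mass_kg" in grp.columns:
            meta["dry_mass_kg"] = grp.iloc[0]["dry_mass_kg"]
        runs.append(
            _run_from_parts(meta, grp["time_min"].to_numpy(), grp["weight_kg"].to_numpy())
        )
    return runs


def write_runs_long_csv(runs: list[DryingRun], path: str | Path) -> None:
    frames = []
    for run in runs:
        df = pd.DataFrame({"time_min": run.times, "weight_kg": run.weights})
        for k, v in _meta_dict(run).items():
            df[k] = v
        frames.append(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_runs(path: str | Path) -> list[DryingRun]:
    """Load runs from a directory of CSV+YAML pairs or a long-format CSV."""
    path = Path(path)
    if path.is_dir():
        csvs = sorted(p for p in path.glob("*.csv"))
        if not csvs:
            raise FileNotFoundError(f"no run CSV files found in {path}")
        return [read_run_csv(p) for p in csvs]
    return read_runs_long_csv(path)
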