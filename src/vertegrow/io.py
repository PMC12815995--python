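"""File schemas, configuration loading, and run manifests.

Tables are CSV (UTF-8, '.' decimal, deterministic column order), configs
are YAML, summaries are JSON.  Pressures cross this boundary in kPa and
angles in degrees; the numeric core uses MPa and radians internally.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .profiles import PhysisProfile
from .synthetic import AnimalRecord

__all__ = [
    "ConfigError",
    "GROWTH_CSV_COLUMNS",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cobb_csv",
    "read_cobb_csv",
    "write_pressures_csv",
    "read_pressures_csv",
    "load_yaml_config",
    "validate_keys",
    "write_json_summary",
    "RunManifest",
    "write_manifest",
]


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


GROWTH_CSV_COLUMNS = [
    "animal_id",
    "cohort",
    "level",
    "physis",
    "x_mm",
    "label_distance_mm",
    "growth_rate_um_day",
    "interval_days",
]


def write_cohort_csv(records: Sequence[AnimalRecord], path) -> Path:
    """One row per station per physis per animal."""
    rows = []
    for rec in records:
        for prof in rec.physes:
            for x, dist, rate in zip(
                prof.positions, prof.label_distance, prof.growth_rate
            ):
                rows.append(
                    {
                        "animal_id": rec.id,
                        "cohort": rec.cohort,
                        "level": prof.vertebra,
                        "physis": prof.side,
                        "x_mm": x,
                        "label_distance_mm": dist,
                        "growth_rate_um_day": rate,
                        "interval_days": prof.interval_days,
                    }
                )
    path = Path(path)
    pd.DataFrame(rows, columns=GROWTH_CSV_COLUMNS).to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> List[AnimalRecord]:
    """Rebuild animal records (measured fields only) from a growth CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ConfigError(f"{path}: file is empty") from exc
    missing = [c for c in GROWTH_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")
    bad = df.index[df[GROWTH_CSV_COLUMNS].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ConfigError(f"{path}: malformed rows at lines {lines}")
    records = []
    for animal_id, adf in df.groupby("animal_id", sort=False):
        physes = []
        for (level, side), pdf in adf.groupby(["level", "physis"], sort=False):
            pdf = pdf.sort_values("x_mm")
            physes.append(
                PhysisProfile(
                    positions=pdf["x_mm"].to_numpy(float),
                    label_distance=pdf["label_distance_mm"].to_numpy(float),
                    growth_rate=pdf["growth_rate_um_day"].to_numpy(float),
                    interval_days=float(pdf["interval_days"].iloc[0]),
                    vertebra=str(level),
                    side=str(side),
                )
            )
        records.append(
            AnimalRecord(
                id=str(animal_id),
                cohort=str(adf["cohort"].iloc[0]),
                physes=physes,
            )
        )
    return records


def write_cobb_csv(series_by_animal: Dict[str, list], path) -> Path:
    rows = [
        {"animal_id": aid, "day": day, "cobb_deg": deg}
        for aid, series in series_by_animal.items()
        for day, deg in series
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["animal_id", "day", "cobb_deg"]).to_csv(
        path, index=False
    )
    return path


def read_cobb_csv(path) -> Dict[str, list]:
    df = pd.read_csv(path)
    return {
        str(aid): list(zip(g["day"].tolist(), g["cobb_deg"].tolist()))
        for aid, g in df.groupby("animal_id", sort=False)
    }


def write_pressures_csv(pressures_by_animal: Dict[str, list], path) -> Path:
    rows = [
        {"animal_id": aid, "disc_id": disc, "pressure_kpa": kpa}
        for aid, items in pressures_by_animal.items()
        for disc, kpa in items
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["animal_id", "disc_id", "pressure_kpa"]).to_csv(
        path, index=False
    )
    return path


def read_pressures_csv(path) -> Dict[str, list]:
    df = pd.read_csv(path)
    return {
        str(aid): list(zip(g["disc_id"].tolist(), g["pressure_kpa"].tolist()))
        for aid, g in df.groupby("animal_id", sort=False)
    }


def validate_keys(mapping: dict, allowed: Sequence[str], context: str) -> None:
    """Reject unknown config keys (typo safety), naming the offending path."""
    unknown = sorted(set(mapping) - set(allowed))
    if unknown:
        raise ConfigError(
            f"unknown key(s) {unknown} at '{context}'; allowed: {sorted(allowed)}"
        )


def load_yaml_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json_summary(data: dict, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(data), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("vertegrow")
    except Exception:  # pragma: no cover - not installed
        return "unknown"


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run."""

    command: str
    config_hash: str
    seed: Optional[int]
    package_version: str
    outputs: List[str] = field(default_factory=list)
    started_utc: str = ""
    finished_utc: str = ""


def config_hash(config: dict) -> str:
    canonical = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def write_manifest(
    out_dir,
    command: str,
    config: dict,
    seed: Optional[int],
    outputs: Sequence[Path],
    started_utc: str,
) -> Path:
    out_dir = Path(out_dir)
    manifest = RunManifest(
        command=command,
        config_hash=config_hash(config),
        seed=seed,
        package_version=_package_version(),
        outputs=sorted(str(Path(p)) for p in outputs),
        started_utc=started_utc,
        finished_utc=datetime.now(timezone.utc).isoformat(),
    )
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def utc_now() -> str:
    return datetime.now(timezone.utc).isoformat()
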