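"""CSV/TOML readers and writers with schema validation.

Counts are stored as integers, never as pre-computed fractions, so that
likelihood evaluations stay exact.  Every writer can attach a JSON sidecar
recording the seed and a hash of the configuration that produced the file.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import pandas as pd

from .cage import ReleaseConfig, Trajectory
from .genetics import DriveParams
from .crosses import VialRecord
from .inference import CageObservations, InferenceResult

__all__ = [
    "read_cage_csv",
    "read_vials_csv",
    "write_vials_csv",
    "write_trajectory_csv",
    "write_result",
    "read_params_toml",
    "write_metadata",
]

CAGE_COLUMNS = ["generation", "n_phenotyped", "n_carriers"]
VIAL_COLUMNS = ["vial_id", "cross_class", "n_offspring", "n_carriers"]


class SchemaError(ValueError):
    """Malformed input table; the message lists offending line numbers."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _int_column(df: pd.DataFrame, col: str, path) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna() | (s != s.round())
    if bad.any():
        lines = [i + 2 for i in df.index[bad]]  # header is line 1
        raise SchemaError(f"{path}: column {col!r} not integral at lines {lines}")
    return s.astype(int)


def read_cage_csv(path, release: ReleaseConfig) -> CageObservations:
    """Read a cage observation table (generation, n_phenotyped, n_carriers)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty cage table")
    _require_columns(df, CAGE_COLUMNS, path)
    for col in CAGE_COLUMNS:
        df[col] = _int_column(df, col, path)
    bad = df["n_carriers"] > df["n_phenotyped"]
    if bad.any():
        lines = [i + 2 for i in df.index[bad]]
        raise SchemaError(f"{path}: n_carriers > n_phenotyped at lines {lines}")
    return CageObservations.from_frame(df, release)


def read_vials_csv(path) -> list[VialRecord]:
    """Read a vial table; optional egg/viability columns are carried along."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty vial table")
    _require_columns(df, VIAL_COLUMNS, path)
    for col in ("n_offspring", "n_carriers"):
        df[col] = _int_column(df, col, path)
    bad = df["n_carriers"] > df["n_offspring"]
    if bad.any():
        lines = [i + 2 for i in df.index[bad]]
        raise SchemaError(f"{path}: n_carriers > n_offspring at lines {lines}")
    egg_cols = [c for c in df.columns if c.startswith("eggs_d")]
    records = []
    for _, row in df.iterrows():
        records.append(
            VialRecord(
                vial_id=str(row["vial_id"]),
                cross_class=str(row["cross_class"]),
                n_offspring=int(row["n_offspring"]),
                n_drive_carriers=int(row["n_carriers"]),
                eggs_per_day=tuple(int(row[c]) for c in egg_cols) or None,
                n_eggs=int(row["n_eggs"]) if "n_eggs" in df.columns else None,
                n_adults=int(row["n_adults"]) if "n_adults" in df.columns else None,
            )
        )
    return records


def write_vials_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_trajectory_csv(path, traj: Trajectory) -> None:
    traj.to_csv(path)


def write_result(path, result: InferenceResult) -> None:
    result.to_json(path)


def read_params_toml(path) -> DriveParams:
    """Drive parameters from a flat TOML table under ``[drive]`` (or top level)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("drive", data)
    known = {
        k: table[k]
        for k in (
            "c_f",
            "c_m",
            "e",
            "f_het",
            "germline_cut_rate",
            "f_het_no_maternal_cas9",
            "split_mode",
        )
        if k in table
    }
    return DriveParams(**known)


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_metadata(path, *, seed, config: dict) -> None:
    """JSON sidecar: seed, configuration, package version, config hash."""
    from . import __version__

    meta = {
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "suppdrive_version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
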