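"""Tabular I/O with validation and reproducibility metadata.

All tables are plain CSV (TSV accepted on read), UTF-8, '.' decimal. Files
written by this package start with comment lines (``# key: value``) carrying
the tool version, the seed and a configuration hash, and are readable back
with any CSV reader that skips ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .devstate import DEFAULT_SCHEMA, ScoringSchema
from .morphometrics import Outline

__all__ = [
    "read_embryo_table",
    "write_table",
    "read_table",
    "read_outline",
    "write_outline",
    "config_hash",
]

REQUIRED_EMBRYO_COLUMNS = ["embryo_id", "strain", "litter_id", "dpc", "weight_mg"]
DPC_RANGE = (11.5, 18.5)


def config_hash(config) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def write_table(df: pd.DataFrame, path, seed=None, config=None) -> Path:
    """Write a DataFrame as CSV/TSV with a metadata comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# molardev: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), comment="#")


def read_embryo_table(path, schema: ScoringSchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Read and validate an embryo table.

    Checks the required columns, positive numeric weights (mg), harvest ages
    within the plausible dpc range, and — when score columns are present —
    integer scores within the schema's ranges. Errors name the offending row
    and column.
    """
    df = read_table(path)
    missing = [c for c in REQUIRED_EMBRYO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    weight = pd.to_numeric(df["weight_mg"], errors="coerce")
    bad = df.index[weight.isna() | (weight <= 0)]
    if len(bad):
        raise ValueError(
            f"{path}: row {bad[0] + 1}, column 'weight_mg': "
            f"non-numeric or non-positive weight {df.loc[bad[0], 'weight_mg']!r}"
        )
    df["weight_mg"] = weight

    dpc = pd.to_numeric(df["dpc"], errors="coerce")
    lo, hi = DPC_RANGE
    bad = df.index[dpc.isna() | (dpc < lo) | (dpc > hi)]
    if len(bad):
        raise ValueError(
            f"{path}: row {bad[0] + 1}, column 'dpc': value "
            f"{df.loc[bad[0], 'dpc']!r} outside [{lo}, {hi}] days"
        )
    df["dpc"] = dpc

    for col, (name, size) in zip(schema.columns, schema.characters):
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & ((vals < 0) | (vals >= size) | (vals % 1 != 0))]
        if len(bad):
            raise ValueError(
                f"{path}: row {bad[0] + 1}, column {col!r}: score "
                f"{df.loc[bad[0], col]!r} outside [0, {size - 1}] for character {name!r}"
            )
    return df


def write_outline(outline: Outline, path, seed=None) -> Path:
    """Write one outline as a CSV of x,y rows (0-based vertex order)."""
    df = pd.DataFrame(outline.points, columns=["x", "y"])
    return write_table(df, path, seed=seed,
                       config={"tooth_id": outline.tooth_id,
                               "tooth_type": outline.tooth_type,
                               "anterior_index": outline.anterior_index})


def read_outline(path, tooth_id=None, tooth_type="UM1", anterior_index=0) -> Outline:
    """Read a per-tooth CSV of x,y rows into an Outline."""
    path = Path(path)
    df = read_table(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: outline file needs 'x' and 'y' columns")
    pts = df[["x", "y"]].to_numpy(float)
    if not np.isfinite(pts).all():
        raise ValueError(f"{path}: non-numeric outline coordinates")
    return Outline(
        points=pts,
        tooth_id=tooth_id or path.stem,
        tooth_type=tooth_type,
        anterior_index=int(anterior_index),
    )
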