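"""CSV/JSON persistence for cell fields.

Cell tables are plain CSV with the canonical header
``id,x_um,y_um,response,covariate,group``; unknown extra columns are
preserved.  Geometry, generator parameters and the RNG seed travel in a
sidecar JSON next to the CSV (``field.csv`` -> ``field.json``) so every field
on disk is fully reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import CSV_COLUMNS, CellField, FieldGeometry


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_field(field: CellField, path: str | Path) -> Path:
    """Write a field as CSV plus a sidecar JSON; returns the CSV path."""
    path = Path(path)
    cols = CSV_COLUMNS + [c for c in field.cells.columns if c not in CSV_COLUMNS]
    # %.17g round-trips float64 exactly
    field.cells[cols].to_csv(path, index=False, float_format="%.17g")
    meta = {
        "geometry": field.geometry.to_dict(),
        "rng_seed": field.rng_seed,
        "params": _jsonable(field.params),
        "n_cells": field.n,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_field(path: str | Path) -> CellField:
    """Read a field CSV (and its sidecar JSON when present).

    Missing required columns and malformed rows raise errors naming the
    column or line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    try:
        cells = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if cells.empty and list(cells.columns) == []:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in CSV_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("x_um", "y_um", "response", "covariate"):
        bad = cells.index[pd.to_numeric(cells[col], errors="coerce").isna() & cells[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {int(bad[0]) + 2}"
            )
        cells[col] = pd.to_numeric(cells[col])
    cells["group"] = cells["group"].fillna("").astype(str)
    cells["id"] = cells["id"].astype(int)

    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        geometry = FieldGeometry.from_dict(meta["geometry"])
        seed = meta.get("rng_seed")
        params = meta.get("params", {})
    else:
        geometry = FieldGeometry(
            width=float(cells["x_um"].max()) if len(cells) else 0.0,
            height=float(cells["y_um"].max()) if len(cells) else 0.0,
        )
        seed, params = None, {}
    return CellField(cells, geometry, rng_seed=seed, params=params)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


__all__ = ["read_field", "write_field", "write_json"]
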