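"""Readers and writers: ASCII-grid rasters, occurrence CSVs, JSON reports.

Rasters use the ESRI ASCII grid format (plain text, self-describing header,
one nodata sentinel), which round-trips float32 values exactly at 9
significant digits and needs no binary dependencies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import NODATA, GridSpec
from .synthetic import OccurrenceRecord

REQUIRED_COLUMNS = ("species", "decimalLongitude", "decimalLatitude")


def write_raster(path, values: np.ndarray, grid: GridSpec) -> None:
    """Write a single-band raster as an ESRI ASCII grid (text).

    Nodata cells (grid mask, NaN, or the NODATA sentinel) are written as the
    sentinel. Rows are stored north to south, as the format requires.
    """
    values = grid.check_layer(np.asarray(values, dtype=np.float32))
    out = values.copy()
    out[grid.nodata_mask] = NODATA
    out[~np.isfinite(out)] = NODATA
    path = Path(path)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.cell_size_km!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.9e")


def read_raster(path, expected_grid: GridSpec | None = None) -> tuple[np.ndarray, GridSpec]:
    """Read an ASCII-grid raster; returns float32 values (NaN on nodata) and
    the grid whose mask marks the nodata cells. Raises if the geometry does
    not match ``expected_grid``."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=np.float32)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(n_rows, n_cols)[::-1]
    nodata = np.float32(header["nodata_value"])
    mask = data == nodata
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_km=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata_mask=mask,
    )
    if expected_grid is not None and not grid.same_geometry(expected_grid):
        raise ValueError(f"raster {path} does not match the expected grid geometry")
    values = data.astype(np.float32)
    values[mask] = np.nan
    return values, grid


@dataclass
class ParseReport:
    n_rows: int
    n_parsed: int
    n_skipped: int


def read_occurrences(path) -> tuple[list[OccurrenceRecord], ParseReport]:
    """Read occurrence records from a Darwin-Core-like CSV.

    Required columns: species, decimalLongitude, decimalLatitude. An
    ``elevation`` column is optional (blank -> missing); an ``is_error``
    column (synthetic provenance) is carried through when present. Rows with
    unparseable or non-finite coordinates are skipped and counted.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    x = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    y = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    elev = (
        pd.to_numeric(df["elevation"], errors="coerce")
        if "elevation" in df.columns
        else pd.Series(np.nan, index=df.index)
    )
    err = (
        df["is_error"].astype(bool)
        if "is_error" in df.columns
        else pd.Series(False, index=df.index)
    )
    ok = np.isfinite(x) & np.isfinite(y)
    records = [
        OccurrenceRecord(
            species=str(df["species"].iloc[i]),
            x=float(x.iloc[i]),
            y=float(y.iloc[i]),
            cited_elevation_m=None if np.isnan(elev.iloc[i]) else float(elev.iloc[i]),
            is_error=bool(err.iloc[i]),
        )
        for i in np.flatnonzero(ok.to_numpy())
    ]
    return records, ParseReport(n_rows=len(df), n_parsed=len(records), n_skipped=int(len(df) - len(records)))


def write_occurrences(path, records: list[OccurrenceRecord]) -> None:
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "decimalLongitude": [r.x for r in records],
            "decimalLatitude": [r.y for r in records],
            "elevation": [r.cited_elevation_m for r in records],
            "is_error": [r.is_error for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
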