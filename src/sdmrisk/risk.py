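"""Quartile-threshold risk-area change between current and scenario maps.

The high-risk threshold is the lower limit of the top quartile (the 75th
percentile, linear interpolation) of present-day suitability over the valid
region. That single threshold reclassifies every scenario map into a binary
high-risk layer; areas and both printed change conventions follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

#: km^2 per grid cell; 100 for the default 10 km x 10 km equal-area cell
DEFAULT_CELL_AREA_KM2 = 100.0


@dataclass
class CellArea:
    km2: float = DEFAULT_CELL_AREA_KM2

    def __post_init__(self) -> None:
        if not self.km2 > 0:
            raise ValueError("cell area must be positive")


def _region_values(values: np.ndarray, grid: GridSpec, region_mask=None) -> np.ndarray:
    mask = grid.valid_mask if region_mask is None else (grid.valid_mask & region_mask)
    vals = np.asarray(values, dtype=float)[mask]
    return vals[np.isfinite(vals)]


def har_threshold(current_map, grid: GridSpec, region_mask=None, q: float = 75.0) -> float:
    """Lower limit of the highest quartile of current suitability over the
    valid region (percentile with linear interpolation between order
    statistics)."""
    vals = _region_values(current_map, grid, region_mask)
    if vals.size < 4:
        raise ValueError("need at least 4 valid cells to take a quartile")
    return float(np.percentile(vals, q))


def classify_har(values, grid: GridSpec, t: float, region_mask=None) -> np.ndarray:
    """Binary high-risk raster: suitability >= t. Returns a float layer with
    1.0 (risk), 0.0 (no risk) and NaN on nodata / out-of-region cells."""
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    mask = grid.valid_mask if region_mask is None else (grid.valid_mask & region_mask)
    vals = np.asarray(values, dtype=float)
    out = np.where(mask & np.isfinite(vals), (vals >= t).astype(float), np.nan)
    return out


def area_km2(binary, cell_area: CellArea | float = DEFAULT_CELL_AREA_KM2) -> float:
    """Risk area: count of risk cells times the per-cell area."""
    a = cell_area.km2 if isinstance(cell_area, CellArea) else float(cell_area)
    binary = np.asarray(binary, dtype=float)
    return float(np.nansum(binary == 1.0) * a)


def change_stats(current_km2: float, future_km2: float) -> dict:
    """Both printed change conventions between a current and a future area.

    ``percent_increase`` is (F - C)/C * 100; ``percent_of_current`` is
    F/C * 100. With C = 0 the percent fields are reported as None. Rounding
    to integer percent is left to the report layer.
    """
    delta = future_km2 - current_km2
    if current_km2 > 0:
        pct_inc = (future_km2 - current_km2) / current_km2 * 100.0
        pct_of = future_km2 / current_km2 * 100.0
    else:
        pct_inc = None
        pct_of = None
    return {
        "delta_km2": delta,
        "percent_increase": pct_inc,
        "percent_of_current": pct_of,
    }


@dataclass
class HARResult:
    threshold: float
    binary_maps: dict[str, np.ndarray]  # scenario label -> binary raster
    areas_km2: dict[str, float]  # scenario label -> km^2 ("current" included)
    changes: dict[str, dict]  # scenario label -> change_stats dict

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "areas_km2": self.areas_km2,
            "changes": self.changes,
        }

    def to_table(self) -> list[dict]:
        """Rows mirroring a current-vs-scenario area table."""
        rows = []
        for label, area in self.areas_km2.items():
            row = {"scenario": label, "area_km2": area}
            if label in self.changes:
                row.update(self.changes[label])
            rows.append(row)
        return rows


def har_report(
    current_map,
    scenario_maps: dict[str, np.ndarray],
    grid: GridSpec,
    region_mask=None,
    cell_area: CellArea | float = DEFAULT_CELL_AREA_KM2,
) -> HARResult:
    """Threshold once on the current map, classify every map with that same
    threshold, and tabulate areas plus both change conventions."""
    current_map = grid.check_layer(np.asarray(current_map, dtype=float))
    for label, sm in scenario_maps.items():
        if np.asarray(sm).shape != grid.shape:
            raise ValueError(f"scenario map {label!r} does not share the grid")
    t = har_threshold(current_map, grid, region_mask)
    binary = {"current": classify_har(current_map, grid, t, region_mask)}
    for label, sm in scenario_maps.items():
        binary[label] = classify_har(np.asarray(sm, dtype=float), grid, t, region_mask)
    areas = {label: area_km2(bm, cell_area) for label, bm in binary.items()}
    changes = {
        label: change_stats(areas["current"], areas[label])
        for label in scenario_maps
    }
    return HARResult(threshold=t, binary_maps=binary, areas_km2=areas, changes=changes)
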