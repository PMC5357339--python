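"""Occurrence-record cleaning and bioclimatic predictor derivation.

Cleaning applies three filters in a fixed order: off-grid removal,
elevation-mismatch removal (strict 100 m tolerance), then one-record-per-cell
deduplication. The three predictors are annual growing degree days (GDD,
base 5 degC on monthly means), the absolute minimum temperature of the
coldest month (Tmin), and annual water balance (WBAL = precipitation minus
Thornthwaite potential evapotranspiration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import NODATA, GridSpec
from .synthetic import DAYS_PER_MONTH, MonthlyClimate, OccurrenceRecord

PREDICTOR_NAMES = ("gdd", "tmin_abs", "wbal")

#: mid-month day-of-year used for day-length in the Thornthwaite PET term
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 344])


@dataclass
class BioclimLayers:
    """The three predictor rasters on one shared grid."""

    gdd: np.ndarray  # degC * day
    tmin_abs: np.ndarray  # degC
    wbal: np.ndarray  # mm / yr
    grid: GridSpec

    def __post_init__(self) -> None:
        for name in PREDICTOR_NAMES:
            self.grid.check_layer(getattr(self, name))
        valid = self.grid.valid_mask
        if np.any(self.gdd[valid] < 0):
            raise ValueError("gdd must be non-negative on valid cells")

    def layers(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in PREDICTOR_NAMES}

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Predictor matrix (n_points, 3) in PREDICTOR_NAMES order."""
        return np.column_stack([getattr(self, name)[rows, cols] for name in PREDICTOR_NAMES])

    def values_valid(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid, 3) predictor matrix over valid cells + flat cell indices."""
        valid_flat = np.flatnonzero(self.grid.valid_mask.ravel())
        rows, cols = np.divmod(valid_flat, self.grid.n_cols)
        return self.values_at_cells(rows, cols), valid_flat


@dataclass
class CleaningReport:
    n_input: int
    n_removed_offgrid: int
    n_removed_elevation: int
    n_removed_duplicate: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_removed_offgrid + self.n_removed_elevation + self.n_removed_duplicate
        if self.n_input != self.n_retained + removed:
            raise ValueError("cleaning counts do not reconcile")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_removed_offgrid": self.n_removed_offgrid,
            "n_removed_elevation": self.n_removed_elevation,
            "n_removed_duplicate": self.n_removed_duplicate,
            "n_retained": self.n_retained,
        }


def drop_offgrid(
    records: list[OccurrenceRecord], grid: GridSpec
) -> tuple[list[OccurrenceRecord], int]:
    """Remove records outside the extent or on nodata cells."""
    kept = []
    for rec in records:
        cell = grid.cell_of(rec.x, rec.y)
        if cell is not None and not grid.nodata_mask[cell]:
            kept.append(rec)
    return kept, len(records) - len(kept)


def elevation_filter(
    records: list[OccurrenceRecord],
    dem: np.ndarray,
    grid: GridSpec,
    tolerance_m: float = 100.0,
) -> tuple[list[OccurrenceRecord], int]:
    """Remove records whose cited elevation differs from the DEM by more than
    ``tolerance_m`` (strictly). Records with no cited elevation are retained;
    records falling on a nodata DEM cell are removed under this filter."""
    grid.check_layer(dem)
    kept = []
    for rec in records:
        cell = grid.cell_of(rec.x, rec.y)
        if cell is None:
            continue  # off-extent records belong to drop_offgrid; drop defensively
        dem_val = dem[cell]
        if dem_val == NODATA or not np.isfinite(dem_val):
            continue
        if rec.cited_elevation_m is None or abs(rec.cited_elevation_m - dem_val) <= tolerance_m:
            kept.append(rec)
    return kept, len(records) - len(kept)


def dedup_cells(
    records: list[OccurrenceRecord], grid: GridSpec
) -> tuple[list[OccurrenceRecord], int]:
    """Keep the first record (in input order) per occupied grid cell."""
    seen: set[tuple[int, int]] = set()
    kept = []
    for rec in records:
        cell = grid.cell_of(rec.x, rec.y)
        if cell is None or cell in seen:
            continue
        seen.add(cell)
        kept.append(rec)
    return kept, len(records) - len(kept)


def clean_records(
    records: list[OccurrenceRecord],
    grid: GridSpec,
    dem: np.ndarray,
    tolerance_m: float = 100.0,
) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Apply the three filters in fixed order and reconcile the counts."""
    n_input = len(records)
    recs, n_off = drop_offgrid(records, grid)
    recs, n_elev = elevation_filter(recs, dem, grid, tolerance_m)
    recs, n_dup = dedup_cells(recs, grid)
    report = CleaningReport(
        n_input=n_input,
        n_removed_offgrid=n_off,
        n_removed_elevation=n_elev,
        n_removed_duplicate=n_dup,
        n_retained=len(recs),
    )
    return recs, report


def growing_degree_days(
    tmean: np.ndarray,
    base_C: float = 5.0,
    days_per_month: np.ndarray | None = None,
) -> np.ndarray:
    """GDD = sum over months of max(0, tmean_m - base) * days_m, cellwise."""
    tmean = np.asarray(tmean, dtype=float)
    if tmean.shape[0] != 12:
        raise ValueError("tmean must have 12 monthly layers")
    days = DAYS_PER_MONTH if days_per_month is None else np.asarray(days_per_month, dtype=float)
    if days.shape != (12,):
        raise ValueError("days_per_month must have 12 entries")
    return np.tensordot(days, np.clip(tmean - base_C, 0.0, None), axes=(0, 0))


def absolute_min_temperature(tmin: np.ndarray) -> np.ndarray:
    """Cellwise minimum over the 12 monthly minimum-temperature layers."""
    tmin = np.asarray(tmin, dtype=float)
    if tmin.shape[0] != 12:
        raise ValueError("tmin must have 12 monthly layers")
    return tmin.min(axis=0)


def day_length_hours(latitude_deg: np.ndarray, doy: int) -> np.ndarray:
    """Mean day length (h) from latitude and day-of-year (standard
    declination / sunset-hour-angle formula, clamped for polar day/night)."""
    lat = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284 + doy) / 365.0)
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def thornthwaite_pet(
    tmean: np.ndarray,
    latitude_deg: np.ndarray,
    days_per_month: np.ndarray | None = None,
) -> np.ndarray:
    """Monthly potential evapotranspiration (mm), Thornthwaite formulation.

    PET_m = 16 * (L_m / 12) * (N_m / 30) * (10 * max(0, T_m) / I) ** a
    with heat index I = sum_m (max(0, T_m) / 5) ** 1.514 and
    a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239.
    PET is zero in months with T_m <= 0, and zero all year where I = 0.
    """
    tmean = np.asarray(tmean, dtype=float)
    if tmean.shape[0] != 12:
        raise ValueError("tmean must have 12 monthly layers")
    days = DAYS_PER_MONTH if days_per_month is None else np.asarray(days_per_month, dtype=float)
    t_pos = np.clip(tmean, 0.0, None)
    heat_index = np.sum((t_pos / 5.0) ** 1.514, axis=0)
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    pet = np.zeros_like(tmean)
    with np.errstate(divide="ignore", invalid="ignore"):
        for m in range(12):
            L = day_length_hours(latitude_deg, int(_MID_MONTH_DOY[m]))
            pet_m = 16.0 * (L / 12.0) * (days[m] / 30.0) * np.where(
                heat_index > 0, (10.0 * t_pos[m] / np.where(heat_index > 0, heat_index, 1.0)) ** a, 0.0
            )
            pet[m] = np.where(t_pos[m] > 0, pet_m, 0.0)
    return pet


def water_balance(
    precip: np.ndarray,
    tmean: np.ndarray,
    latitude_layer: np.ndarray,
    days_per_month: np.ndarray | None = None,
) -> np.ndarray:
    """Annual water balance: sum over months of (precip_m - PET_m), in mm.

    Can be negative in warm dry climates; equals annual precipitation where
    every month is at or below freezing (PET vanishes there).
    """
    precip = np.asarray(precip, dtype=float)
    if precip.shape[0] != 12:
        raise ValueError("precip must have 12 monthly layers")
    pet = thornthwaite_pet(tmean, latitude_layer, days_per_month)
    return (precip - pet).sum(axis=0)


def derive_bioclim(climate: MonthlyClimate, base_C: float = 5.0) -> BioclimLayers:
    """Compute the GDD / Tmin / WBAL predictor stack from monthly climate."""
    return BioclimLayers(
        gdd=growing_degree_days(climate.tmean, base_C=base_C),
        tmin_abs=absolute_min_temperature(climate.tmin),
        wbal=water_balance(climate.precip, climate.tmean, climate.latitude_layer),
        grid=climate.grid,
    )
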