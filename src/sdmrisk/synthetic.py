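"""Synthetic climate, elevation, ground-truth suitability and occurrence records.

Everything is seeded and deterministic so downstream stages can be tested
against known ground truth without any external data downloads. Random
fields are Gaussian noise smoothed with a fixed-width moving average plus a
deterministic north-south gradient, which gives spatially autocorrelated,
climate-like layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.special import expit

from .grid import NODATA, GridSpec

DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

#: Latitude (deg N) assigned to y = origin_y. The synthetic world is
#: compressed north-south (20 km per degree) so a few-hundred-row grid spans
#: subtropical-to-subarctic climates.
LAT_AT_ORIGIN = 30.0
KM_PER_DEGREE = 20.0


@dataclass
class MonthlyClimate:
    """Twelve monthly rasters of mean/min temperature and precipitation."""

    tmean: np.ndarray  # (12, R, C) degC
    tmin: np.ndarray  # (12, R, C) degC
    precip: np.ndarray  # (12, R, C) mm
    latitude_layer: np.ndarray  # (R, C) degrees, needed for PET day length
    grid: GridSpec

    def __post_init__(self) -> None:
        for name in ("tmean", "tmin", "precip"):
            arr = getattr(self, name)
            if arr.shape != (12, *self.grid.shape):
                raise ValueError(f"{name} must have shape (12, n_rows, n_cols)")
        self.grid.check_layer(self.latitude_layer)
        if np.any(self.tmin > self.tmean):
            raise ValueError("tmin must be <= tmean in every month and cell")
        if np.any(self.precip < 0):
            raise ValueError("precip must be non-negative")


@dataclass
class TruthParams:
    """Coefficients of the known logistic suitability surface.

    Applied to standardized (zero-mean, unit-variance over valid cells)
    predictors, so they are unitless.
    """

    intercept: float = 0.0
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    seed: int = 0


@dataclass
class OccurrenceRecord:
    species: str
    x: float  # km, equal-area plane
    y: float  # km
    cited_elevation_m: float | None = None
    is_error: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if self.cited_elevation_m is not None and self.cited_elevation_m < -500:
            raise ValueError("cited elevation below -500 m")


def latitude_layer(grid: GridSpec) -> np.ndarray:
    """Latitude (deg) of each cell center, increasing northwards with y."""
    lat_rows = LAT_AT_ORIGIN + grid.y_centers() / KM_PER_DEGREE
    return np.broadcast_to(lat_rows[:, None], grid.shape).copy()


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], width: int | None = None) -> np.ndarray:
    """Zero-mean spatially autocorrelated noise, roughly unit scale."""
    if width is None:
        width = max(3, min(shape) // 8)
    noise = rng.standard_normal(shape)
    smoothed = uniform_filter(noise, size=width, mode="nearest")
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def generate_climate(
    grid: GridSpec,
    seed: int,
    warming_offset_C: float = 0.0,
    precip_factor: float = 1.0,
) -> MonthlyClimate:
    """Smooth seeded monthly climate with a sinusoidal seasonal cycle.

    A future scenario is the same seeded base climate with
    ``warming_offset_C`` added to both temperature stacks and precipitation
    multiplied by ``precip_factor``, so scenario deltas are exact by
    construction.
    """
    if not precip_factor > 0:
        raise ValueError("precip_factor must be positive")
    rng = np.random.default_rng(seed)
    lat = latitude_layer(grid)

    # annual-mean temperature: cooler northwards, plus smooth local anomaly
    t_annual = 25.0 - 0.6 * (lat - LAT_AT_ORIGIN) + 2.0 * _smooth_field(rng, grid.shape)
    # strong independent amplitude variation decorrelates the coldest-month
    # minimum from the annual thermal sum
    amplitude = 10.0 + 3.0 * _smooth_field(rng, grid.shape)
    # positive diurnal offset separating tmin from tmean
    diurnal = 4.0 + 2.0 * np.abs(_smooth_field(rng, grid.shape))
    precip_base = 60.0 + 25.0 * _smooth_field(rng, grid.shape)
    precip_season = 15.0 + 5.0 * _smooth_field(rng, grid.shape)

    months = np.arange(12)
    # peak warmth in July (m=6), minimum in January
    cycle = -np.cos(2.0 * np.pi * (months + 0.5) / 12.0)

    tmean = t_annual[None] + amplitude[None] * cycle[:, None, None] + warming_offset_C
    tmin = tmean - diurnal[None]
    precip = np.clip(
        precip_base[None] + precip_season[None] * cycle[:, None, None], 0.0, None
    ) * precip_factor
    return MonthlyClimate(tmean=tmean, tmin=tmin, precip=precip, latitude_layer=lat, grid=grid)


def generate_elevation(grid: GridSpec, seed: int) -> np.ndarray:
    """Smooth non-negative elevation (m); NODATA on masked cells."""
    rng = np.random.default_rng(seed)
    elev = np.clip(500.0 + 350.0 * _smooth_field(rng, grid.shape), 0.0, None)
    elev[grid.nodata_mask] = NODATA
    return elev


def _standardize(layer: np.ndarray, valid: np.ndarray) -> np.ndarray:
    vals = layer[valid]
    sd = vals.std()
    if sd == 0:
        return np.zeros_like(layer)
    return (layer - vals.mean()) / sd


def true_suitability(bioclim, params: TruthParams) -> np.ndarray:
    """Known logistic suitability over standardized predictors; NaN on nodata.

    ``bioclim`` is any object exposing ``layers()`` -> dict[name, raster]
    and ``grid`` (see :class:`sdmrisk.preprocess.BioclimLayers`).
    """
    grid: GridSpec = bioclim.grid
    valid = grid.valid_mask
    if not valid.any():
        raise ValueError("all cells are nodata")
    layers = bioclim.layers()
    eta = np.full(grid.shape, params.intercept, dtype=float)
    for name, coef in params.linear.items():
        if coef != 0:
            eta += coef * _standardize(layers[name], valid)
    for name, coef in params.quadratic.items():
        if coef != 0:
            eta += coef * _standardize(layers[name], valid) ** 2
    suit = expit(eta)
    suit[~valid] = np.nan
    return suit


def sample_occurrences(
    truth: np.ndarray,
    grid: GridSpec,
    elevation: np.ndarray,
    n: int,
    seed: int,
    error_rates: dict[str, float] | None = None,
    species: str = "synthetic_sp",
) -> list[OccurrenceRecord]:
    """Presence records sampled proportional to ``truth``, plus seeded errors.

    Clean records land on valid cells with per-cell probability proportional
    to suitability, uniformly placed within the cell, with a cited elevation
    within +-100 m of the cell's elevation (so they survive all cleaning
    filters except in-cell deduplication). Error records are flagged
    ``is_error``: off-grid points (on nodata cells, or outside the extent if
    the grid has none), elevation mismatches offset by more than 100 m, and
    duplicates copied into an already-sampled cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rates = {"offgrid": 0.0, "elev_mismatch": 0.0, "duplicate": 0.0}
    if error_rates:
        rates.update(error_rates)
    for k, v in rates.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"error rate {k} outside [0, 1]")
    if sum(rates.values()) > 1.0:
        raise ValueError("error rates must sum to <= 1")

    rng = np.random.default_rng(seed)
    valid = grid.valid_mask
    probs = np.where(valid, np.nan_to_num(truth, nan=0.0), 0.0).ravel()
    total = probs.sum()
    if total <= 0:
        raise ValueError("truth suitability is zero everywhere")
    probs = probs / total

    counts = rng.multinomial(
        n,
        [
            rates["offgrid"],
            rates["elev_mismatch"],
            rates["duplicate"],
            1.0 - sum(rates.values()),
        ],
    )
    n_off, n_mis, n_dup, n_clean = (int(c) for c in counts)
    s = grid.cell_size_km

    def point_in_cell(i: int, j: int) -> tuple[float, float]:
        x = grid.origin_x + (j + rng.uniform(0.0, 1.0)) * s
        y = grid.origin_y + (i + rng.uniform(0.0, 1.0)) * s
        return x, y

    records: list[OccurrenceRecord] = []
    clean_cells: list[tuple[int, int]] = []
    flat = rng.choice(grid.n_cells, size=n_clean, replace=True, p=probs)
    for idx in flat:
        i, j = divmod(int(idx), grid.n_cols)
        x, y = point_in_cell(i, j)
        elev = float(elevation[i, j]) + rng.uniform(-99.0, 99.0)
        records.append(OccurrenceRecord(species, x, y, max(elev, -499.0), is_error=False))
        clean_cells.append((i, j))

    # duplicates: extra records dropped into cells that already hold one
    for _ in range(n_dup):
        if clean_cells:
            i, j = clean_cells[int(rng.integers(len(clean_cells)))]
        else:  # degenerate call with no clean records: any valid cell
            idx = int(rng.choice(grid.n_cells, p=probs))
            i, j = divmod(idx, grid.n_cols)
        x, y = point_in_cell(i, j)
        elev = float(elevation[i, j]) + rng.uniform(-99.0, 99.0)
        records.append(OccurrenceRecord(species, x, y, max(elev, -499.0), is_error=True))

    # elevation mismatches: valid cell but cited elevation off by >100 m
    valid_flat = np.flatnonzero(valid.ravel())
    for _ in range(n_mis):
        idx = int(valid_flat[rng.integers(valid_flat.size)])
        i, j = divmod(idx, grid.n_cols)
        x, y = point_in_cell(i, j)
        offset = (101.0 + rng.uniform(0.0, 500.0)) * (1 if rng.random() < 0.5 else -1)
        elev = max(float(elevation[i, j]) + offset, -499.0)
        records.append(OccurrenceRecord(species, x, y, elev, is_error=True))

    # off-grid: nodata cells when available, else outside the extent
    nodata_flat = np.flatnonzero(grid.nodata_mask.ravel())
    for _ in range(n_off):
        if nodata_flat.size:
            idx = int(nodata_flat[rng.integers(nodata_flat.size)])
            i, j = divmod(idx, grid.n_cols)
            x, y = point_in_cell(i, j)
        else:
            x = grid.origin_x - (1.0 + rng.uniform(0.0, 5.0)) * s
            y = grid.origin_y - (1.0 + rng.uniform(0.0, 5.0)) * s
        records.append(OccurrenceRecord(species, x, y, None, is_error=True))

    # deterministic seeded shuffle so error records are interleaved
    order = rng.permutation(len(records))
    return [records[i] for i in order]
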