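"""Equal-area raster grid geometry shared by every layer in a run."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel written to rasters on invalid ("sea") cells.
NODATA = -9999.0


@dataclass
class GridSpec:
    """Geometry of an equal-area raster grid.

    Coordinates are kilometres in an equal-area plane. Cell ``(i, j)``
    spans ``x in [origin_x + j*s, origin_x + (j+1)*s)`` and
    ``y in [origin_y + i*s, origin_y + (i+1)*s)`` with ``s = cell_size_km``;
    row 0 is the southernmost row.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 10.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must have at least 2 rows and 2 columns")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.shape:
                raise ValueError(
                    f"nodata_mask shape {self.nodata_mask.shape} != grid shape {self.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell index containing point ``(x, y)``, or None if off the extent."""
        j = int(np.floor((x - self.origin_x) / self.cell_size_km))
        i = int(np.floor((y - self.origin_y) / self.cell_size_km))
        if 0 <= i < self.n_rows and 0 <= j < self.n_cols:
            return (i, j)
        return None

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        s = self.cell_size_km
        return (self.origin_x + (j + 0.5) * s, self.origin_y + (i + 0.5) * s)

    def y_centers(self) -> np.ndarray:
        """y coordinate (km) of each row's cell centers."""
        s = self.cell_size_km
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * s

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size_km == other.cell_size_km
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
        )

    def check_layer(self, layer: np.ndarray) -> np.ndarray:
        """Validate that ``layer`` matches this grid's shape; returns the array."""
        layer = np.asarray(layer)
        if layer.shape != self.shape:
            raise ValueError(f"layer shape {layer.shape} != grid shape {self.shape}")
        return layer
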