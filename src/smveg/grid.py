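"""Core raster containers shared by every analysis stage.

A :class:`BasinGeometry` fixes the grid shape, cell size, origin and the
outside-basin mask; every raster produced by the pipeline carries the same
geometry object and any geometry mismatch raises before computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


def nanmean_quiet(a, axis=None):
    """np.nanmean that treats all-NaN slices as NaN without warning."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(a, axis=axis)

SEASONS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),  # Dec of year-1, Jan/Feb of the labelled year
}


class GeometryError(ValueError):
    """Raised when rasters with incompatible geometries are combined."""


@dataclass(frozen=True)
class BasinGeometry:
    """Grid shape, resolution and basin mask shared by all rasters.

    ``nodata_mask`` is True OUTSIDE the basin (cells excluded from every
    statistic). ``origin`` is the map coordinate of the upper-left corner;
    row 0 is the northern edge, the last row the southern edge.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError(
                f"grid must be at least 8x8, got {self.n_rows}x{self.n_cols}"
            )
        if self.nodata_mask is None:
            object.__setattr__(
                self, "nodata_mask", np.zeros((self.n_rows, self.n_cols), dtype=bool)
            )
        mask = np.asarray(self.nodata_mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise GeometryError("nodata_mask shape does not match grid dimensions")
        object.__setattr__(self, "nodata_mask", mask)
        self.nodata_mask.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, row 0 = north."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def __eq__(self, other):
        if not isinstance(other, BasinGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
            and np.array_equal(self.nodata_mask, other.nodata_mask)
        )

    def __hash__(self):
        return hash((self.shape, self.cell_size, self.origin))


@dataclass
class RasterGrid:
    """Single-band float grid; NaN marks nodata inside the array."""

    data: np.ndarray
    geometry: BasinGeometry
    name: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float).copy()
        if data.shape != self.geometry.shape:
            raise GeometryError(
                f"data shape {data.shape} does not match geometry {self.geometry.shape}"
            )
        data[self.geometry.nodata_mask] = np.nan
        self.data = data

    @property
    def values(self) -> np.ndarray:
        """1-D array of the finite values inside the basin."""
        v = self.data[~self.geometry.nodata_mask]
        return v[np.isfinite(v)]

    def with_data(self, data: np.ndarray, name: str | None = None) -> "RasterGrid":
        return RasterGrid(data, self.geometry, self.name if name is None else name)

    def rescaled(self, name: str | None = None) -> "RasterGrid":
        """Min-max rescale of in-basin values to [0, 1]."""
        v = self.values
        if v.size == 0:
            raise ValueError("raster has no valid cells to rescale")
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            out = np.where(np.isfinite(self.data), 0.5, np.nan)
        else:
            out = (self.data - lo) / (hi - lo)
        return self.with_data(out, name)


def check_same_geometry(*grids: RasterGrid) -> BasinGeometry:
    """Return the shared geometry or raise :class:`GeometryError`."""
    geom = grids[0].geometry
    for g in grids[1:]:
        if g.geometry != geom:
            detail = (
                "nodata masks differ"
                if g.geometry.shape == geom.shape
                and g.geometry.cell_size == geom.cell_size
                and g.geometry.origin == geom.origin
                else "grid frames differ"
            )
            raise GeometryError(
                f"geometry mismatch ({detail}): {geom.shape}@{geom.cell_size} vs "
                f"{g.geometry.shape}@{g.geometry.cell_size}"
            )
    return geom


def check_same_frame(*grids: RasterGrid) -> None:
    """Require matching shape/resolution/origin but allow differing masks."""
    ref = grids[0].geometry
    for g in grids[1:]:
        same = (
            g.geometry.shape == ref.shape
            and g.geometry.cell_size == ref.cell_size
            and g.geometry.origin == ref.origin
        )
        if not same:
            raise GeometryError(
                f"grid frames differ: {ref.shape}@{ref.cell_size} vs "
                f"{g.geometry.shape}@{g.geometry.cell_size}"
            )
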