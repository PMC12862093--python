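"""Temporal quality control and compositing of monthly raster stacks.

The processing chain mirrors standard optical time-series hygiene: flag
cloud/snow-like outliers with a radiometric floor plus a temporal spike
rule, reconstruct flagged values by linear interpolation in time, then
maximum-value composite (MVC) within each window, and finally aggregate to
meteorological seasons (spring Mar-May, summer Jun-Aug, autumn Sep-Nov,
winter Dec-Feb, with December counted toward the following year's winter)
or annual means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import SEASONS, BasinGeometry, GeometryError, RasterGrid, nanmean_quiet

log = logging.getLogger("smveg")


@dataclass
class TimeSeriesStack:
    """Ordered monthly grids of one variable on a shared geometry.

    ``data`` has shape (T, rows, cols) with NaN as nodata; ``times`` is a
    strictly increasing list of (year, month).
    """

    variable: str
    times: list[tuple[int, int]]
    data: np.ndarray
    geometry: BasinGeometry

    def __post_init__(self):
        if self.data.shape != (len(self.times), *self.geometry.shape):
            raise GeometryError("stack data shape does not match times/geometry")
        keys = [y * 12 + m for y, m in self.times]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("times must be strictly increasing")
        data = np.asarray(self.data, dtype=float).copy()
        data[:, self.geometry.nodata_mask] = np.nan
        self.data = data

    @classmethod
    def from_arrays(cls, variable, times, data, geometry) -> "TimeSeriesStack":
        return cls(variable, list(times), np.asarray(data, dtype=float), geometry)

    @classmethod
    def from_grids(cls, variable, times, grids) -> "TimeSeriesStack":
        geom = grids[0].geometry
        for g in grids[1:]:
            if g.geometry != geom:
                raise GeometryError("stack layers have mismatched geometry")
        return cls(variable, list(times), np.stack([g.data for g in grids]), geom)

    def __len__(self) -> int:
        return len(self.times)

    def grid(self, i: int) -> RasterGrid:
        y, m = self.times[i]
        return RasterGrid(self.data[i], self.geometry, f"{self.variable}_{y}_{m:02d}")

    def grids(self) -> list[RasterGrid]:
        return [self.grid(i) for i in range(len(self))]

    def select(self, indices) -> "TimeSeriesStack":
        indices = list(indices)
        return TimeSeriesStack(
            self.variable,
            [self.times[i] for i in indices],
            self.data[indices],
            self.geometry,
        )


def flag_outliers(
    stack: TimeSeriesStack, low_threshold: float = 0.0, spike_factor: float = 2.0
) -> np.ndarray:
    """Boolean (T, rows, cols) array of suspect cell-times.

    A value is flagged when it falls below ``low_threshold`` (radiometric
    floor) or, at interior time steps, when it deviates from the mean of its
    two temporal neighbours by more than ``spike_factor`` times the absolute
    difference of those neighbours (so any bump over a flat neighbourhood is
    a spike). Endpoints are tested against the floor only.
    """
    if len(stack) < 3:
        raise ValueError("outlier flagging needs at least 3 time steps")
    v = stack.data
    flags = v < low_threshold
    prev, nxt = v[:-2], v[2:]
    mid = v[1:-1]
    neighbor_mean = 0.5 * (prev + nxt)
    neighbor_range = np.abs(prev - nxt)
    with np.errstate(invalid="ignore"):
        spike = np.abs(mid - neighbor_mean) > spike_factor * neighbor_range
    flags[1:-1] |= spike & np.isfinite(mid) & np.isfinite(neighbor_mean)
    flags[~np.isfinite(v)] = False  # nodata is absent, not an outlier
    return flags


def linear_gapfill(stack: TimeSeriesStack, flags: np.ndarray) -> TimeSeriesStack:
    """Replace flagged values by linear interpolation along the time axis.

    Boundary gaps take the nearest valid value. Cells (or cell-times already
    nodata) with fewer than two valid observations become all-nodata and are
    logged.
    """
    if flags.shape != stack.data.shape:
        raise ValueError("flags shape must match stack")
    t = np.arange(len(stack), dtype=float)
    out = stack.data.copy()
    valid = np.isfinite(stack.data) & ~flags
    flat_out = out.reshape(len(stack), -1)
    flat_valid = valid.reshape(len(stack), -1)
    n_dropped = 0
    for j in np.flatnonzero(~flat_valid.all(axis=0)):
        vj = flat_valid[:, j]
        if vj.sum() < 2:
            if np.isfinite(flat_out[:, j]).any():
                n_dropped += 1
            flat_out[:, j] = np.nan
            continue
        flat_out[~vj, j] = np.interp(t[~vj], t[vj], flat_out[vj, j])
    if n_dropped:
        log.warning("gap-fill: %d cells had <2 valid observations -> nodata", n_dropped)
    return TimeSeriesStack(stack.variable, list(stack.times), out, stack.geometry)


def mvc_composite(stack: TimeSeriesStack, indices=None) -> RasterGrid:
    """Cellwise maximum over the window (all layers by default)."""
    sub = stack.data if indices is None else stack.data[list(indices)]
    if sub.shape[0] == 0:
        raise ValueError("empty compositing window")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        comp = np.nanmax(sub, axis=0)  # all-NaN cells stay nodata
    return RasterGrid(comp, stack.geometry, f"{stack.variable}_mvc")


def _month_indices(stack: TimeSeriesStack, wanted: list[tuple[int, int]]):
    lookup = {t: i for i, t in enumerate(stack.times)}
    missing = [t for t in wanted if t not in lookup]
    if missing:
        raise ValueError(f"stack is missing required months: {missing}")
    return [lookup[t] for t in wanted]


def seasonal_aggregate(stack: TimeSeriesStack, season: str, year: int) -> RasterGrid:
    """Cellwise mean over the season's three months.

    Winter of year y uses December of y-1 with January and February of y.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    months = SEASONS[season]
    wanted = [(year - 1 if m == 12 else year, m) for m in months]
    idx = _month_indices(stack, wanted)
    mean = nanmean_quiet(stack.data[idx], axis=0)
    return RasterGrid(mean, stack.geometry, f"{stack.variable}_{season}_{year}")


def annual_mean(stack: TimeSeriesStack, year: int) -> RasterGrid:
    """Cellwise mean over the 12 calendar months of ``year``."""
    wanted = [(year, m) for m in range(1, 13)]
    idx = _month_indices(stack, wanted)
    mean = nanmean_quiet(stack.data[idx], axis=0)
    return RasterGrid(mean, stack.geometry, f"{stack.variable}_annual_{year}")
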