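"""Raster and table I/O.

Rasters are stored as single-band float32 TIFF files with nodata −9999 and
the grid geometry (cell size, origin) serialized as JSON in the TIFF
ImageDescription tag, so a file round-trips to an identical
:class:`~smveg.grid.RasterGrid`. Stacks live on disk as one file per month
named ``<var>_<YYYY>_<MM>.tif``.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import NODATA, BasinGeometry, RasterGrid

log = logging.getLogger("smveg")

_STACK_RE = re.compile(r"^(?P<var>.+)_(?P<year>\d{4})_(?P<month>\d{2})\.tif$")


def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.where(np.isfinite(grid.data), grid.data, NODATA).astype(np.float32)
    meta = {
        "cell_size": grid.geometry.cell_size,
        "origin": list(grid.geometry.origin),
        "nodata": NODATA,
        "name": grid.name,
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))
    return path


def read_raster(path: str | Path) -> RasterGrid:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(np.float64)
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if "cell_size" not in meta:
        log.warning("%s carries no geometry metadata; assuming unit local grid", path)
    nodata = meta.get("nodata", NODATA)
    mask = ~np.isfinite(data) | (data == nodata)
    geom = BasinGeometry(
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        cell_size=float(meta.get("cell_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata_mask=mask,
    )
    data = data.copy()
    data[mask] = np.nan
    return RasterGrid(data, geom, name=meta.get("name", path.stem))


def write_stack(stack, directory: str | Path) -> Path:
    """Write a TimeSeriesStack as per-month files ``<var>_<YYYY>_<MM>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (year, month), grid in zip(stack.times, stack.grids()):
        write_raster(grid, directory / f"{stack.variable}_{year:04d}_{month:02d}.tif")
    return directory


def read_stack(directory: str | Path, variable: str):
    """Assemble a TimeSeriesStack from ``<var>_<YYYY>_<MM>.tif`` files."""
    from .timeseries import TimeSeriesStack  # local import to avoid a cycle

    directory = Path(directory)
    entries = []
    for p in sorted(directory.iterdir()):
        m = _STACK_RE.match(p.name)
        if m and m.group("var") == variable:
            entries.append(((int(m.group("year")), int(m.group("month"))), p))
    if not entries:
        raise FileNotFoundError(f"no '{variable}_YYYY_MM.tif' files in {directory}")
    entries.sort(key=lambda e: e[0])
    grids = [read_raster(p) for _, p in entries]
    return TimeSeriesStack.from_grids(variable, [t for t, _ in entries], grids)


def write_samples(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def sample_at_points(grid: RasterGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Nearest-cell raster values at map coordinates (outside grid -> NaN)."""
    x0, y0 = grid.geometry.origin
    cols = np.floor((np.asarray(x) - x0) / grid.geometry.cell_size).astype(int)
    rows = np.floor((y0 - np.asarray(y)) / grid.geometry.cell_size).astype(int)
    out = np.full(cols.shape, np.nan)
    ok = (
        (rows >= 0)
        & (rows < grid.geometry.n_rows)
        & (cols >= 0)
        & (cols < grid.geometry.n_cols)
    )
    out[ok] = grid.data[rows[ok], cols[ok]]
    return out
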