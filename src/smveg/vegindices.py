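"""Spectral vegetation indices computed cellwise from reflectance grids.

All formulas operate on [0, 1] reflectances from the blue (B2), green (B3),
red (B4) and near-infrared (B8) bands. Cells whose denominator vanishes
become nodata so downstream statistics stay finite; nodata in any input
propagates to the output.
"""

from __future__ import annotations

import numpy as np

from .grid import RasterGrid, check_same_geometry


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
    out[ok] = num[ok] / den[ok]
    return out


def ndvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """(NIR - Red) / (NIR + Red)."""
    check_same_geometry(nir, red)
    return nir.with_data(_ratio(nir.data - red.data, nir.data + red.data), "NDVI")


def evi(nir: RasterGrid, red: RasterGrid, blue: RasterGrid) -> RasterGrid:
    """2.5 (NIR - Red) / (NIR + 6 Red - 7.5 Blue + 1)."""
    check_same_geometry(nir, red, blue)
    den = nir.data + 6.0 * red.data - 7.5 * blue.data + 1.0
    return nir.with_data(_ratio(2.5 * (nir.data - red.data), den), "EVI")


def savi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """1.5 (NIR - Red) / (NIR + Red + 0.5), soil-adjustment factor L = 0.5."""
    check_same_geometry(nir, red)
    den = nir.data + red.data + 0.5
    return nir.with_data(_ratio(1.5 * (nir.data - red.data), den), "SAVI")


def dvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """NIR - Red."""
    check_same_geometry(nir, red)
    return nir.with_data(nir.data - red.data, "DVI")


def rvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """NIR / Red."""
    check_same_geometry(nir, red)
    return nir.with_data(_ratio(nir.data, red.data), "RVI")


def arvi(nir: RasterGrid, red: RasterGrid, blue: RasterGrid) -> RasterGrid:
    """(NIR - (2 Red - Blue)) / (NIR + (2 Red - Blue)).

    Substituting 2 Red - Blue for Red in the NDVI form suppresses aerosol
    effects, which matters over built-up areas.
    """
    check_same_geometry(nir, red, blue)
    rb = 2.0 * red.data - blue.data
    return nir.with_data(_ratio(nir.data - rb, nir.data + rb), "ARVI")


def gndvi(nir: RasterGrid, green: RasterGrid) -> RasterGrid:
    """(NIR - Green) / (NIR + Green)."""
    check_same_geometry(nir, green)
    return nir.with_data(_ratio(nir.data - green.data, nir.data + green.data), "GNDVI")


#: index name -> (function, band names in call order)
INDEX_BANDS = {
    "NDVI": (ndvi, ("B8", "B4")),
    "EVI": (evi, ("B8", "B4", "B2")),
    "SAVI": (savi, ("B8", "B4")),
    "DVI": (dvi, ("B8", "B4")),
    "RVI": (rvi, ("B8", "B4")),
    "ARVI": (arvi, ("B8", "B4", "B2")),
    "GNDVI": (gndvi, ("B8", "B3")),
}


def compute_index(name: str, bands: dict[str, RasterGrid]) -> RasterGrid:
    """Compute a named index from a band dictionary (keys B2, B3, B4, B8)."""
    key = name.upper()
    if key not in INDEX_BANDS:
        raise KeyError(f"unknown index {name!r}; choose from {sorted(INDEX_BANDS)}")
    func, needed = INDEX_BANDS[key]
    missing = [b for b in needed if b not in bands]
    if missing:
        raise KeyError(f"{key} needs bands {missing} which are not in the input")
    grid = func(*(bands[b] for b in needed))
    if grid.values.size == 0:
        raise ValueError(f"{key}: no valid cells in input bands")
    return grid
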