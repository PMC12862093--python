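"""Per-pixel Spearman rank correlation between two raster time series.

The coefficient is the Pearson correlation of mid-ranks; two-sided p values
come from t = rho sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom, the
usual approximation which is exact in neither tail for very short series
(with 8 annual layers the test is low-powered; n is reported alongside p).
Pixels are classified at a significance level into significant-positive,
significant-negative and non-significant, with area proportions over the
basin. No across-pixel multiplicity correction is applied by default;
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import BasinGeometry, RasterGrid
from .timeseries import TimeSeriesStack

CLASS_NODATA, CLASS_NONSIG, CLASS_POS, CLASS_NEG = -1, 0, 1, 2
CLASS_NAMES = {CLASS_POS: "sig+", CLASS_NEG: "sig-", CLASS_NONSIG: "nonsig"}


def _rho_p_from_ranks(r1: np.ndarray, r2: np.ndarray, n: int):
    r1c = r1 - r1.mean(axis=0)
    r2c = r2 - r2.mean(axis=0)
    den = np.sqrt((r1c**2).sum(axis=0) * (r2c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (r1c * r2c).sum(axis=0) / den
    rho = np.where(den > 0, rho, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isfinite(rho), p, np.nan)
    return rho, p


def spearman_pixel(sm_series, veg_series) -> tuple[float, float]:
    """Spearman rho and two-sided t-based p for one pixel's series.

    Ties receive mid-ranks; |rho| = 1 maps to p = 0; a constant series has
    no defined rank correlation and yields NaN.
    """
    a = np.asarray(sm_series, dtype=float)
    b = np.asarray(veg_series, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and the same length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho, p = _rho_p_from_ranks(ra[:, None], rb[:, None], n)
    return float(rho[0]), float(p[0])


@dataclass
class CorrelationMaps:
    rho: RasterGrid
    p: RasterGrid
    n: int
    classes: np.ndarray  # int grid with CLASS_* codes
    alpha: float

    @property
    def geometry(self) -> BasinGeometry:
        return self.rho.geometry


def correlate_stacks(
    sm_stack: TimeSeriesStack,
    veg_stack: TimeSeriesStack,
    alpha: float = 0.05,
    fdr: bool = False,
) -> CorrelationMaps:
    """Pixel-wise Spearman correlation of two aligned stacks.

    Stacks must share geometry and time axis. ``fdr=True`` applies a
    Benjamini-Hochberg adjustment across basin pixels before classifying.
    """
    if veg_stack.geometry != sm_stack.geometry:
        raise ValueError("stacks have mismatched geometry")
    if veg_stack.times != sm_stack.times:
        raise ValueError(f"stacks misaligned in time: {sm_stack.times[:3]}... vs {veg_stack.times[:3]}...")
    n = len(sm_stack)
    if n < 3:
        raise ValueError("need at least 3 time steps")
    geom = sm_stack.geometry
    a = sm_stack.data.reshape(n, -1)
    b = veg_stack.data.reshape(n, -1)
    finite = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    nonconst = finite & (np.ptp(a, axis=0) > 0) & (np.ptp(b, axis=0) > 0)
    ra = stats.rankdata(a, axis=0)
    rb = stats.rankdata(b, axis=0)
    rho, p = _rho_p_from_ranks(ra, rb, n)
    rho[~nonconst] = np.nan
    p[~nonconst] = np.nan

    p_class = p.copy()
    if fdr:
        idx = np.flatnonzero(np.isfinite(p))
        if idx.size:
            p_class[idx] = stats.false_discovery_control(p[idx])

    classes = np.full(a.shape[1], CLASS_NODATA, dtype=np.int8)
    ok = np.isfinite(rho)
    sig = ok & (p_class < alpha)
    classes[ok] = CLASS_NONSIG
    classes[sig & (rho > 0)] = CLASS_POS
    classes[sig & (rho < 0)] = CLASS_NEG

    shape = geom.shape
    return CorrelationMaps(
        rho=RasterGrid(rho.reshape(shape), geom, "spearman_rho"),
        p=RasterGrid(p.reshape(shape), geom, "spearman_p"),
        n=n,
        classes=classes.reshape(shape),
        alpha=alpha,
    )


def area_proportions(maps: CorrelationMaps) -> dict[str, float]:
    """Fractions of basin pixels per significance class (sum to 1)."""
    inside = ~maps.geometry.nodata_mask
    cls = maps.classes[inside]
    cls = cls[cls != CLASS_NODATA]
    if cls.size == 0:
        raise ValueError("no classified pixels inside the basin")
    return {
        name: float((cls == code).mean()) for code, name in CLASS_NAMES.items()
    }
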