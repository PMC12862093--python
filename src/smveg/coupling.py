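"""Coupling-coordination analysis of two subsystem scores.

For vegetation score VEG and soil-moisture score SM (both in [0, 1]):

    C = 2 sqrt(VEG * SM) / (VEG + SM)      coupling degree (balance)
    T = alpha * VEG + beta * SM            harmonization index, alpha+beta=1
    D = sqrt(C * T)                        coupling coordination degree

C is 1 exactly when the two scores are equal and positive, 0 when either
vanishes, and undefined (nodata) when both are 0. D is binned into five
ordinal levels on half-open intervals (low, high]: Extreme Disorder
(0, 0.2], Mild Disorder (0.2, 0.4], Barely Coordinated (0.4, 0.6],
Moderately Coordinated (0.6, 0.8], Highly Coordinated (0.8, 1.0]. D = 0 is
assigned to Extreme Disorder by convention. A harmonic-mean form of C,
2 VEG SM / (VEG + SM), is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid, check_same_geometry

log = logging.getLogger("smveg")

CLASS_NAMES = (
    "Extreme Disorder",
    "Mild Disorder",
    "Barely Coordinated",
    "Moderately Coordinated",
    "Highly Coordinated",
)
CLASS_BOUNDS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def _as_array(x):
    return x.data if isinstance(x, RasterGrid) else np.asarray(x, dtype=float)


def _check_unit_range(name, a):
    finite = a[np.isfinite(a)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(f"{name} values must lie in [0, 1]")


def coupling_degree(veg, sm, form: str = "sqrt"):
    """Coupling degree C of the two subsystem scores.

    ``form='sqrt'`` is the canonical 2 sqrt(VEG SM)/(VEG+SM);
    ``form='harmonic'`` uses 2 VEG SM/(VEG+SM). Both-zero cells are nodata.
    """
    v, s = _as_array(veg), _as_array(sm)
    _check_unit_range("VEG", v)
    _check_unit_range("SM", s)
    den = v + s
    with np.errstate(invalid="ignore", divide="ignore"):
        if form == "sqrt":
            c = 2.0 * np.sqrt(v * s) / den
        elif form == "harmonic":
            c = 2.0 * v * s / den
        else:
            raise ValueError("form must be 'sqrt' or 'harmonic'")
    c = np.where(den > 0, c, np.nan)
    if isinstance(veg, RasterGrid):
        check_same_geometry(veg, sm)
        return veg.with_data(c, "C")
    return c


def harmonization(veg, sm, alpha: float = 0.5, beta: float = 0.5):
    """Harmonization index T = alpha VEG + beta SM with alpha + beta = 1."""
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    v, s = _as_array(veg), _as_array(sm)
    t = alpha * v + beta * s
    if isinstance(veg, RasterGrid):
        check_same_geometry(veg, sm)
        return veg.with_data(t, "T")
    return t


def ccd(c, t):
    """Coupling coordination degree D = sqrt(C * T)."""
    ca, ta = _as_array(c), _as_array(t)
    _check_unit_range("C", ca)
    _check_unit_range("T", ta)
    d = np.sqrt(ca * ta)
    if isinstance(c, RasterGrid):
        return c.with_data(d, "D")
    return d


def classify(d):
    """Ordinal class (1..5) of D on half-open intervals (low, high].

    Returns an int array (0 marks nodata). D = 0 is put in class 1.
    """
    a = _as_array(d)
    finite = np.isfinite(a)
    if finite.any() and (a[finite].min() < 0 or a[finite].max() > 1):
        raise ValueError("D must lie in [0, 1]")
    # right-closed bins: class k iff bounds[k-1] < D <= bounds[k]
    cls = np.zeros(a.shape, dtype=np.int8)
    for k in range(1, 6):
        lo, hi = CLASS_BOUNDS[k - 1], CLASS_BOUNDS[k]
        cls[finite & (a > lo) & (a <= hi)] = k
    zero = finite & (a == 0.0)
    if zero.any():
        log.info("classify: %d cells with D=0 assigned to Extreme Disorder", zero.sum())
        cls[zero] = 1
    return cls


def class_area_proportions(classes: np.ndarray, geometry=None) -> dict[str, float]:
    """Fraction of classified basin pixels per coordination level (sums to 1)."""
    cls = np.asarray(classes)
    if geometry is not None:
        cls = cls[~geometry.nodata_mask]
    cls = cls[cls > 0]
    if cls.size == 0:
        raise ValueError("no classified pixels")
    return {name: float((cls == k + 1).mean()) for k, name in enumerate(CLASS_NAMES)}


@dataclass
class CouplingMaps:
    c: RasterGrid
    t: RasterGrid
    d: RasterGrid
    classes: np.ndarray
    proportions: dict[str, float]
    alpha: float
    beta: float
    form: str


def couple_grids(
    veg: RasterGrid,
    sm: RasterGrid,
    alpha: float = 0.5,
    beta: float = 0.5,
    form: str = "sqrt",
    rescale: bool = True,
) -> CouplingMaps:
    """Full coupling analysis of a vegetation and a soil-moisture grid.

    With ``rescale`` the inputs are min-max rescaled to [0, 1] subsystem
    scores first (the convention used throughout the pipeline; the raw-scale
    alternative is available because the choice shifts class fractions).
    """
    check_same_geometry(veg, sm)
    if rescale:
        veg, sm = veg.rescaled("VEG"), sm.rescaled("SM")
    c = coupling_degree(veg, sm, form=form)
    t = harmonization(veg, sm, alpha, beta)
    d = ccd(c, t)
    classes = classify(d)
    props = class_area_proportions(classes, d.geometry)
    log.info("coupling: form=%s alpha=%.2f beta=%.2f proportions=%s", form, alpha, beta, props)
    return CouplingMaps(c, t, d, classes, props, alpha, beta, form)
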