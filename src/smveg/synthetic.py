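"""Synthetic basin generator.

Emulates the statistical structure the downstream analysis assumes: an
irregular connected basin on a regular grid, a north-dry/south-wet moisture
gradient, seasonal vegetation cycles peaking in summer, soil samples whose
moisture follows known linear equations on physicochemical predictors plus
Gaussian noise, cross-correlated vegetation descriptors, and driver rasters
combined into a latent coordination field with a planted importance order.

Defaults encode the study conditions: 170 sites split over three depth
layers, soil-moisture truth equations

    SM(0-10cm)  = -0.105 + 0.013 P_cap + 0.084 BD
    SM(10-20cm) = -0.123 + 0.012 P_cap + 0.101 BD + 0.002 TP + 0.016 TK
                  + 0.000004 B12 - 0.00001 B6
    SM(20-30cm) = -0.115 + 0.013 P_cap + 0.091 BD

(P_cap in %, BD in g cm^-3, TP/TK in g kg^-1, optical bands in DN), and a
driver-importance profile dominated by land-surface temperature and
potential evapotranspiration.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import BasinGeometry, RasterGrid

DEPTH_LAYERS = ("0-10", "10-20", "20-30")

#: default soil-moisture truth: intercept + linear coefficients per depth layer
SM_TRUTH_COEFFICIENTS = {
    "0-10": {"intercept": -0.105, "P_cap": 0.013, "BD": 0.084},
    "10-20": {
        "intercept": -0.123,
        "P_cap": 0.012,
        "BD": 0.101,
        "TP": 0.002,
        "TK": 0.016,
        "B12": 0.000004,
        "B6": -0.00001,
    },
    "20-30": {"intercept": -0.115, "P_cap": 0.013, "BD": 0.091},
}

OPTICAL_BANDS = ("B2", "B3", "B4", "B6", "B8", "B8A", "B11", "B12")
RADAR_BANDS = ("VH", "VV")

DRIVER_NAMES = (
    "pop_density",
    "elevation",
    "slope",
    "aspect",
    "temperature",
    "precipitation",
    "lst",
    "pet",
)

#: realistic value ranges per driver (units in the DriverSample contract)
_DRIVER_RANGES = {
    "pop_density": (0.0, 500.0),
    "elevation": (1500.0, 3300.0),
    "slope": (0.0, 40.0),
    "aspect": (0.0, 360.0),
    "temperature": (2.0, 10.0),
    "precipitation": (300.0, 600.0),
    "lst": (275.0, 305.0),
    "pet": (600.0, 1100.0),
}

#: default planted importance order and per-driver latent weights: the two
#: thermal/evaporative drivers tied at the top, then geometric 0.5 decay
#: (ratio 1:1:0.5:0.25:...), which yields a combined top-two Gini share near
#: one half with the remaining drivers ordered as planted.
DEFAULT_PLANTED_ORDER = (
    "lst",
    "pet",
    "precipitation",
    "temperature",
    "elevation",
    "pop_density",
    "slope",
    "aspect",
)
DEFAULT_PLANTED_WEIGHTS = (1.0, 1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625)


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Derive a per-stage generator so stages reproduce independently."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])


@dataclass
class TruthConfig:
    """Generative truth for soil samples."""

    coefficients: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in SM_TRUTH_COEFFICIENTS.items()}
    )
    noise_sd: float = 0.01
    gradient_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for depth, coefs in self.coefficients.items():
            for name, c in coefs.items():
                if not np.isfinite(c):
                    raise ValueError(f"non-finite coefficient {name} at depth {depth}")

    def evaluate(self, depth: str, row) -> float:
        coefs = self.coefficients[depth]
        sm = coefs["intercept"]
        for name, c in coefs.items():
            if name != "intercept":
                sm += c * row[name]
        return sm


def _smooth_field(shape, rng, sigma) -> np.ndarray:
    """Standardized smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    return (f - f.mean()) / f.std()


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def generate_geometry(
    n_rows: int, n_cols: int, cell_size: float = 20.0, seed: int = 0
) -> BasinGeometry:
    """Irregular connected basin mask covering at least half the grid.

    Built from a smoothed Gaussian field minus a radial penalty so the basin
    hugs the grid center with a ragged boundary.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("basin grid must be at least 8x8")
    rng = child_rng(seed, "geometry")
    f = _smooth_field((n_rows, n_cols), rng, sigma=max(min(n_rows, n_cols) / 8.0, 1.5))
    rr, cc = np.meshgrid(
        np.linspace(-1, 1, n_rows), np.linspace(-1, 1, n_cols), indexing="ij"
    )
    score = 0.6 * f - 1.2 * (rr**2 + cc**2)
    inside = None
    for q in (0.35, 0.3, 0.25, 0.2, 0.15, 0.1, 0.05, 0.0):
        cand = _largest_component(score >= np.quantile(score, q))
        if cand.mean() >= 0.5:
            inside = cand
            break
    if inside is None:  # pragma: no cover - q=0 keeps everything
        inside = np.ones((n_rows, n_cols), dtype=bool)
    return BasinGeometry(n_rows, n_cols, cell_size, (0.0, 0.0), ~inside)


def _southness(geometry: BasinGeometry) -> np.ndarray:
    """0 at the northern edge (row 0) to 1 at the southern edge."""
    rows = np.linspace(0.0, 1.0, geometry.n_rows)[:, None]
    return np.broadcast_to(rows, geometry.shape).copy()


def latent_fields(geometry: BasinGeometry, seed: int, gradient_strength: float = 1.0):
    """Basin-wide wetness and vegetation base fields in [0, 1].

    Both share the north-dry/south-wet trend so soil moisture and vegetation
    are spatially coupled, each with its own smooth texture.
    """
    rng = child_rng(seed, "fields")
    south = _southness(geometry)
    sigma = max(min(geometry.shape) / 10.0, 1.5)
    wet = gradient_strength * south + 0.45 * _smooth_field(geometry.shape, rng, sigma)
    veg = gradient_strength * south + 0.45 * _smooth_field(geometry.shape, rng, sigma)
    anomaly = _smooth_field(geometry.shape, rng, sigma)

    def unit(a):
        return (a - a.min()) / (a.max() - a.min())

    return unit(wet), unit(veg), anomaly


def _year_anomaly(seed: int, year: int) -> float:
    return float(child_rng(seed, f"year-{year}").normal(0.0, 0.08))


def _season_factor(month: int) -> float:
    """Seasonal modulation in [0.35, 1], peaking at mid-year (month 7)."""
    return 0.35 + 0.65 * 0.5 * (1.0 - np.cos(2.0 * np.pi * (month - 7) / 12.0 + np.pi))


def _band_fields(wetness, veg, month, rng):
    """Reflectance ([0, 1]) and radar (dB) fields from the latent surfaces."""
    ndvi = np.clip(
        0.05 + 0.8 * veg * _season_factor(month) + 0.02 * rng.standard_normal(veg.shape),
        -0.2,
        0.9,
    )
    b8 = 0.22 * (1.0 + ndvi)
    b4 = 0.22 * (1.0 - ndvi)
    eps = lambda s: s * rng.standard_normal(veg.shape)
    bands = {
        "B8": b8,
        "B4": b4,
        "B2": np.clip(0.8 * b4 + 0.01 + eps(0.005), 0, 1),
        "B3": np.clip(0.5 * (b4 + b8) * 0.6 + eps(0.005), 0, 1),
        "B6": np.clip(0.5 * (b4 + b8) + eps(0.01), 0, 1),
        "B8A": np.clip(1.02 * b8 + eps(0.005), 0, 1),
        "B11": np.clip(0.40 - 0.22 * wetness + eps(0.01), 0, 1),
        "B12": np.clip(0.35 - 0.20 * wetness + eps(0.01), 0, 1),
        "VH": np.clip(-25.0 + 12.0 * wetness + eps(0.6), -30, 0),
        "VV": np.clip(-18.0 + 10.0 * wetness + eps(0.6), -30, 0),
    }
    bands["B8"] = np.clip(b8, 0, 1)
    bands["B4"] = np.clip(b4, 0, 1)
    return bands


def generate_band_stack(
    geometry: BasinGeometry,
    month_index: int,
    seed: int = 0,
    year: int = 2017,
    gradient_strength: float = 1.0,
) -> dict[str, RasterGrid]:
    """One month of spectral/radar bands sharing the basin geometry.

    Reflectance bands lie in [0, 1], radar backscatter in [-30, 0] dB; NDVI
    computed from B8/B4 is higher in the southern half and peaks mid-year.
    """
    if not 1 <= month_index <= 12:
        raise ValueError("month_index must be in 1..12")
    wet, veg, anom = latent_fields(geometry, seed, gradient_strength)
    a = _year_anomaly(seed, year)
    wet_y = np.clip(wet + a * (0.6 + 0.4 * anom), 0, 1)
    veg_y = np.clip(veg + 0.7 * a * (0.6 + 0.4 * anom), 0, 1)
    rng = child_rng(seed, f"bands-{year}-{month_index}")
    fields = _band_fields(wet_y, veg_y, month_index, rng)
    return {k: RasterGrid(v, geometry, name=k) for k, v in fields.items()}


def generate_vegetation_products(
    geometry: BasinGeometry,
    month_index: int,
    seed: int = 0,
    year: int = 2017,
    gradient_strength: float = 1.0,
) -> dict[str, RasterGrid]:
    """Monthly NPP (gC m^-2) and LAI grids co-varying with the canopy field."""
    _, veg, anom = latent_fields(geometry, seed, gradient_strength)
    a = _year_anomaly(seed, year)
    veg_y = np.clip(veg + 0.7 * a * (0.6 + 0.4 * anom), 0, 1)
    s = _season_factor(month_index)
    rng = child_rng(seed, f"products-{year}-{month_index}")
    npp = np.clip(20.0 + 90.0 * veg_y * s + 3.0 * rng.standard_normal(veg.shape), 0, None)
    lai = np.clip(0.2 + 5.5 * veg_y * s + 0.15 * rng.standard_normal(veg.shape), 0, None)
    return {
        "NPP": RasterGrid(npp, geometry, name="NPP"),
        "LAI": RasterGrid(lai, geometry, name="LAI"),
    }


def generate_soil_samples(
    n_sites: int,
    truth: TruthConfig,
    geometry: BasinGeometry | None = None,
) -> pd.DataFrame:
    """Per-site, per-depth soil physicochemistry with known moisture truth.

    Three depth layers per site; moisture is the truth equation evaluated on
    the drawn predictors plus Gaussian noise, clipped to [0, 1]. Optical band
    columns are stored in DN (reflectance x 10^4), matching the scale of the
    truth-equation band coefficients; radar columns are in dB.
    """
    if n_sites < 20:
        raise ValueError("need at least 20 sites for a 4:1 split plus stepwise fitting")
    rng = child_rng(truth.seed, "samples")

    if geometry is not None:
        wet, _, _ = latent_fields(geometry, truth.seed, truth.gradient_strength)
        rows_in, cols_in = np.where(~geometry.nodata_mask)
        pick = rng.choice(len(rows_in), size=n_sites, replace=len(rows_in) < n_sites)
        r, c = rows_in[pick], cols_in[pick]
        x0, y0 = geometry.origin
        x = x0 + (c + 0.5) * geometry.cell_size
        y = y0 - (r + 0.5) * geometry.cell_size
        w = wet[r, c]
    else:
        x = rng.uniform(0, 1000, n_sites)
        y = rng.uniform(-1000, 0, n_sites)
        w = rng.uniform(0, 1, n_sites)

    # soil properties share the wetness signal with signs matching the truth
    # equations, so bulk density and porosity are the strongest moisture
    # correlates and the nutrients are consistent but weaker ones
    u = lambda: rng.uniform(0, 1, n_sites)
    p_cap = np.clip(30.0 + 30.0 * (0.5 * w + 0.5 * u()), 30, 60)
    bd = np.clip(0.9 + 0.7 * (0.5 * w + 0.5 * u()), 0.9, 1.6)
    p_non = np.clip(2.0 + 13.0 * (0.3 * w + 0.7 * u()), 2, 15)
    tn = 0.5 + 2.5 * (0.4 * w + 0.6 * u())
    tp = 0.4 + 0.8 * (0.3 * w + 0.7 * u())
    tk = 14.0 + 11.0 * (0.3 * w + 0.7 * u())
    ak = 50.0 + 200.0 * (0.4 * w + 0.6 * u())
    tex = rng.dirichlet((2.0, 5.0, 3.0), n_sites) * 100.0

    noise = lambda s: s * rng.standard_normal(n_sites)
    b12_refl = np.clip(0.35 - 0.20 * w + noise(0.01), 0, 1)
    b11_refl = np.clip(0.40 - 0.22 * w + noise(0.01), 0, 1)
    b8_refl = np.clip(0.25 + 0.10 * w + noise(0.01), 0, 1)
    b4_refl = np.clip(0.20 - 0.05 * w + noise(0.01), 0, 1)
    bands = {
        "B2": np.clip(0.8 * b4_refl + 0.01 + noise(0.005), 0, 1),
        "B3": np.clip(0.5 * (b4_refl + b8_refl) * 0.6 + noise(0.005), 0, 1),
        "B4": b4_refl,
        "B6": np.clip(0.5 * (b4_refl + b8_refl) + noise(0.01), 0, 1),
        "B8": b8_refl,
        "B8A": np.clip(1.02 * b8_refl + noise(0.005), 0, 1),
        "B11": b11_refl,
        "B12": b12_refl,
    }
    vh = np.clip(-25.0 + 12.0 * w + noise(0.6), -30, 0)
    vv = np.clip(-18.0 + 10.0 * w + noise(0.6), -30, 0)

    base = pd.DataFrame(
        {
            "site": np.arange(n_sites),
            "x": x,
            "y": y,
            "BD": bd,
            "P_cap": p_cap,
            "P_non": p_non,
            "TN": tn,
            "TP": tp,
            "TK": tk,
            "AK": ak,
            "clay": tex[:, 0],
            "silt": tex[:, 1],
            "sand": tex[:, 2],
            **{k: v * 1e4 for k, v in bands.items()},
            "VH": vh,
            "VV": vv,
        }
    )

    frames = []
    for depth in DEPTH_LAYERS:
        df = base.copy()
        df.insert(3, "depth", depth)
        sm = df.apply(lambda row: truth.evaluate(depth, row), axis=1).to_numpy()
        if truth.noise_sd > 0:
            sm = sm + rng.normal(0.0, truth.noise_sd, n_sites)
        df["SM"] = np.clip(sm, 0.0, 1.0)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class DriverStack:
    """Eight driver rasters, the latent coordination field they generate, and
    the planted importance order/weights used to build it."""

    drivers: dict[str, RasterGrid]
    latent: RasterGrid
    planted_order: tuple[str, ...]
    weights: tuple[float, ...]


def generate_driver_stack(
    geometry: BasinGeometry,
    planted_order: tuple[str, ...] = DEFAULT_PLANTED_ORDER,
    seed: int = 0,
    weights: tuple[float, ...] | None = None,
    weight_decay: float | None = None,
    noise_sd: float = 0.35,
    anchor: RasterGrid | None = None,
) -> DriverStack:
    """Driver rasters plus a latent coordination field with planted importance.

    Without an anchor, the latent field is a weighted sum of the z-scored
    drivers with weights decreasing along ``planted_order`` (default: the
    sqrt-share profile; pass ``weight_decay`` for a geometric sequence or
    ``weights`` explicitly), plus Gaussian noise, min-max rescaled into
    [0.05, 0.95]. With an ``anchor`` grid (e.g. the basin's wetness field),
    the roles invert: each driver is built to correlate with the anchor in
    proportion to its planted weight and the anchor itself becomes the
    latent field, so a coordination map derived from the same truth depends
    on the drivers with the planted strengths.
    """
    if sorted(planted_order) != sorted(DRIVER_NAMES):
        raise ValueError(f"planted_order must be a permutation of {DRIVER_NAMES}")
    if weights is None:
        if weight_decay is not None:
            weights = tuple(weight_decay**i for i in range(len(planted_order)))
        else:
            weights = DEFAULT_PLANTED_WEIGHTS
    if len(weights) != len(planted_order):
        raise ValueError("one weight per driver required")

    rng = child_rng(seed, "drivers")
    # finer texture than the wetness/vegetation fields: drivers need enough
    # spatial degrees of freedom for importance recovery to be identifiable
    sigma = 2.0
    w_by_name = dict(zip(planted_order, weights))
    if anchor is not None:
        a = anchor.data.copy()
        a_z = (a - np.nanmean(a)) / np.nanstd(a)
        a_z = np.where(np.isfinite(a_z), a_z, 0.0)
        w_max = max(weights)
    drivers: dict[str, RasterGrid] = {}
    z_fields: dict[str, np.ndarray] = {}
    for name in DRIVER_NAMES:
        f = _smooth_field(geometry.shape, rng, sigma)
        if anchor is not None:
            rho = w_by_name[name] / w_max * 0.9
            f = rho * a_z + np.sqrt(1.0 - rho**2) * f
        z_fields[name] = f
        lo, hi = _DRIVER_RANGES[name]
        u = (f - f.min()) / (f.max() - f.min())
        drivers[name] = RasterGrid(lo + (hi - lo) * u, geometry, name=name)

    if anchor is not None:
        latent = a_z
    else:
        latent = sum(w * z_fields[name] for name, w in zip(planted_order, weights))
        latent = latent + noise_sd * rng.standard_normal(geometry.shape)
    latent = (latent - latent.min()) / (latent.max() - latent.min())
    latent = 0.05 + 0.90 * latent
    return DriverStack(
        drivers=drivers,
        latent=RasterGrid(latent, geometry, name="latent_d"),
        planted_order=tuple(planted_order),
        weights=tuple(float(w) for w in weights),
    )


def generate_coupled_stacks(
    geometry: BasinGeometry,
    years=range(2017, 2025),
    seed: int = 0,
    noise_sd: float = 0.03,
):
    """Annual SM and VEG stacks with a planted correlation split.

    Both track a common interannual signal; in the southern half VEG follows
    the signal (positive coupling), in the northern half it opposes it.
    Returns ``(sm_stack, veg_stack)`` as TimeSeriesStacks with one layer per
    year.
    """
    from .timeseries import TimeSeriesStack

    years = list(years)
    rng = child_rng(seed, "coupled")
    signal = rng.normal(0.0, 1.0, len(years))
    south = _southness(geometry) >= 0.5
    sm_layers, veg_layers = [], []
    for s_t in signal:
        eps = lambda: noise_sd * rng.standard_normal(geometry.shape)
        sm = np.clip(0.45 + 0.12 * s_t + eps(), 0, 1)
        veg = np.where(
            south, 0.45 + 0.12 * s_t, 0.45 - 0.12 * s_t
        ) + eps()
        sm_layers.append(sm)
        veg_layers.append(np.clip(veg, 0, 1))
    times = [(y, 1) for y in years]
    sm_stack = TimeSeriesStack.from_arrays("SM", times, np.array(sm_layers), geometry)
    veg_stack = TimeSeriesStack.from_arrays("VEG", times, np.array(veg_layers), geometry)
    return sm_stack, veg_stack
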