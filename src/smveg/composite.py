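"""Composite vegetation index construction.

A site-by-indicator matrix (NPP, LAI and one spectral index) is z-scored
and screened with the Kaiser-Meyer-Olkin sampling-adequacy measure and
Bartlett's test of sphericity; principal components are extracted from the
correlation matrix, retained by the Kaiser rule (optionally extended until
a cumulative-variance target), varimax-rotated, and converted to component
score coefficients by the regression method (R^-1 x rotated loadings). The
per-indicator composite weights combine the score-coefficient columns in
proportion to the rotated sums of squared loadings and are normalized to
sum to one; the composite raster is the weighted sum of min-max rescaled
indicator grids, so it stays in [0, 1] for the coupling model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from .grid import RasterGrid, check_same_geometry

log = logging.getLogger("smveg")


def kmo(corr: np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal elements, where q
    are the anti-image partial correlations. An identity correlation matrix
    has no shared variance: KMO is returned as 0 and logged.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    r2 = float((R[off] ** 2).sum())
    if r2 == 0.0:
        log.warning("KMO degenerate: identity correlation matrix (no shared variance)")
        return 0.0
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    q = -Rinv / d
    q2 = float((q[off] ** 2).sum())
    return r2 / (r2 + q2)


def bartlett(corr: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity against an identity correlation matrix.

    chi2 = -(n - 1 - (2p + 5)/6) ln|R| with p(p-1)/2 degrees of freedom.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("Bartlett's test needs more observations than variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix determinant is not positive")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


@dataclass
class PcaResult:
    """Correlation-matrix PCA with varimax rotation of retained components."""

    indicators: list[str]
    eigenvalues: np.ndarray          # all p, descending
    pct_variance: np.ndarray
    cumulative_pct: np.ndarray
    loadings: np.ndarray             # unrotated, p x n_retained
    rotated_loadings: np.ndarray
    rotated_ss_loadings: np.ndarray  # per retained component
    score_coefficients: np.ndarray   # p x n_retained
    communalities: np.ndarray
    n_retained: int
    correlation: np.ndarray = field(repr=False, default=None)


def pca(
    matrix: pd.DataFrame | np.ndarray,
    indicators: list[str] | None = None,
    cumulative_target: float = 0.90,
) -> PcaResult:
    """Eigen-PCA of the correlation matrix with Kaiser-plus-target retention.

    Components with eigenvalue > 1 are retained; further components are added
    while the cumulative explained variance is below ``cumulative_target``.
    Loadings are eigenvectors scaled by sqrt(eigenvalue); the retained block
    is varimax-rotated (Kaiser-normalized) and score coefficients follow the
    regression method. Communalities are row sums of squared retained
    loadings, invariant under rotation.
    """
    if isinstance(matrix, pd.DataFrame):
        indicators = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if indicators is None:
            indicators = [f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than indicators")
    if p < 2:
        raise ValueError("need at least 2 indicators")
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    pct = 100.0 * eigval / p
    cum = np.cumsum(pct)

    n_ret = max(1, int((eigval > 1.0).sum()))
    while n_ret < p and cum[n_ret - 1] < cumulative_target * 100.0:
        n_ret += 1

    loadings = eigvec[:, :n_ret] * np.sqrt(eigval[:n_ret])
    # fix sign convention: dominant direction of each component positive
    signs = np.sign(loadings.sum(axis=0))
    signs[signs == 0] = 1.0
    loadings = loadings * signs

    if n_ret > 1:
        rotated, _ = rotate_factors(loadings, "varimax")
        rsigns = np.sign(rotated.sum(axis=0))
        rsigns[rsigns == 0] = 1.0
        rotated = rotated * rsigns
        rot_order = np.argsort(-(rotated**2).sum(axis=0))
        rotated = rotated[:, rot_order]
    else:
        rotated = loadings.copy()
    rss = (rotated**2).sum(axis=0)
    # pseudo-inverse: degenerate correlation matrices (perfectly collinear
    # indicators) get the minimum-norm score coefficients instead of failing
    score_coefs = np.linalg.pinv(R, rcond=1e-8) @ rotated
    communalities = (loadings**2).sum(axis=1)
    return PcaResult(
        indicators=indicators,
        eigenvalues=eigval,
        pct_variance=pct,
        cumulative_pct=cum,
        loadings=loadings,
        rotated_loadings=rotated,
        rotated_ss_loadings=rss,
        score_coefficients=score_coefs,
        communalities=communalities,
        n_retained=n_ret,
        correlation=R,
    )


def combine_score_coefficients(
    score_coefficients: np.ndarray, component_weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Combine per-component score coefficients into normalized weights.

    Each component contributes in proportion to its share of the rotated
    sums of squared loadings: combined_i = sum_k (lambda_k / sum lambda) *
    coef_ik; weights are the combined coefficients normalized to sum to 1.
    A negative combined coefficient is normalized as-is and flagged.
    """
    S = np.atleast_2d(np.asarray(score_coefficients, dtype=float))
    lam = np.asarray(component_weights, dtype=float)
    combined = S @ (lam / lam.sum())
    flags = []
    if np.any(combined < 0):
        flags.append("negative combined coefficient; normalized over raw values")
        log.warning("composite weights: %s", flags[0])
    weights = combined / combined.sum()
    return weights, combined, flags


def composite_weights(result: PcaResult):
    """Normalized composite-index weights from a fitted PCA."""
    weights, combined, flags = combine_score_coefficients(
        result.score_coefficients, result.rotated_ss_loadings
    )
    return pd.Series(weights, index=result.indicators, name="weight"), flags


def select_best_index(
    candidates: dict[str, np.ndarray],
    npp: np.ndarray,
    lai: np.ndarray,
    r_gate: float = 0.6,
    kmo_gate: float = 0.5,
    alpha: float = 0.05,
) -> tuple[str, pd.DataFrame]:
    """Choose the spectral index to pair with NPP and LAI.

    For each candidate the triple (candidate, NPP, LAI) is assembled; the
    candidate maximizing KMO is chosen among those with Bartlett p < alpha,
    KMO above ``kmo_gate`` and max |r| with LAI or NPP above ``r_gate``. If
    none qualifies, the best-KMO candidate is returned flagged.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate indices")
    rows = []
    for name, vals in candidates.items():
        X = np.column_stack([np.asarray(vals, float), np.asarray(npp, float), np.asarray(lai, float)])
        ok = np.isfinite(X).all(axis=1)
        X = X[ok]
        R = np.corrcoef(X, rowvar=False)
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0 or logdet < -80:
            # perfectly collinear triple: sphericity is rejected trivially and
            # the anti-image needs a slightly shrunk matrix to be computable
            p_bart = 0.0
            k = kmo(0.999999 * R + 1e-6 * np.eye(R.shape[0]))
        else:
            k = kmo(R)
            _, _, p_bart = bartlett(R, X.shape[0])
        r_lai = abs(R[0, 2])
        r_npp = abs(R[0, 1])
        passes = (k >= kmo_gate) and (p_bart < alpha) and (max(r_lai, r_npp) > r_gate)
        rows.append((name, k, p_bart, r_npp, r_lai, passes))
    report = pd.DataFrame(
        rows, columns=["index", "kmo", "bartlett_p", "r_npp", "r_lai", "passes"]
    ).set_index("index")
    passing = report[report["passes"]]
    pool = passing if len(passing) else report
    if not len(passing):
        log.warning("no candidate index passed the KMO/Bartlett/correlation gates")
    return pool["kmo"].idxmax(), report


def veg_raster(weights: pd.Series, grids: dict[str, RasterGrid]) -> RasterGrid:
    """Composite index raster: weighted sum of min-max rescaled indicators."""
    missing = [k for k in weights.index if k not in grids]
    if missing:
        raise KeyError(f"missing indicator grids: {missing}")
    glist = [grids[k] for k in weights.index]
    geom = check_same_geometry(*glist)
    out = np.zeros(geom.shape)
    for name, w in weights.items():
        out = out + w * grids[name].rescaled().data
    return RasterGrid(out, geom, name="VEG")
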