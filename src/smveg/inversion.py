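"""Soil-moisture regression inversion per depth layer.

Workflow: Pearson screening of candidate predictors against measured
moisture, a seeded 4:1 train/validation split at site level, three model
families (significance-based stepwise linear regression, ridge regression
with cross-validated penalty, partial least squares with cross-validated
component count), error metrics on the held-out split, a rule-based choice
among the families, and wall-to-wall raster prediction with soil-property
surfaces interpolated from the sample points by inverse-distance weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm_api
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .grid import BasinGeometry, RasterGrid, check_same_geometry

log = logging.getLogger("smveg")

#: columns that are never predictors
_META_COLUMNS = {"site", "x", "y", "depth", "SM"}

#: validation gates used for model choice
GATES = {"rmse": 0.05, "mae": 0.02, "mape": 20.0}

_METHOD_ORDER = {"SMLR": 0, "Ridge": 1, "PLSR": 2}


@dataclass
class FittedModel:
    method: str
    depth: str
    intercept: float
    coefficients: dict[str, float]
    hyperparameters: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        pred = np.full(len(table), self.intercept, dtype=float)
        for name, c in self.coefficients.items():
            pred += c * table[name].to_numpy(dtype=float)
        return pred


@dataclass
class EvaluationReport:
    method: str
    depth: str
    r2: float
    rmse: float
    mae: float
    mape: float
    p_value: float
    n_train: int
    n_valid: int

    def passes_gates(self, gates: dict = None) -> bool:
        g = GATES if gates is None else gates
        return (
            self.rmse < g["rmse"]
            and self.mae < g["mae"]
            and np.isfinite(self.mape)
            and 0.0 <= self.mape < g["mape"]
        )


def candidate_predictors(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


def screen_predictors(
    table: pd.DataFrame, depth: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson r and two-sided p of each candidate against SM for one depth.

    Returns a frame indexed by predictor with columns r, p, retained, sorted
    by |r| descending. Constant predictors are excluded and logged. The p
    value comes from the t distribution with n-2 degrees of freedom.
    """
    sub = table[table["depth"] == depth]
    if len(sub) < 10:
        raise ValueError(f"need at least 10 rows for depth {depth}, got {len(sub)}")
    y = sub["SM"].to_numpy(dtype=float)
    rows = []
    for name in candidate_predictors(sub):
        x = sub[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            log.info("screen: predictor %s is constant at depth %s, excluded", name, depth)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((name, r, p, p < alpha))
    out = pd.DataFrame(rows, columns=["predictor", "r", "p", "retained"])
    out = out.set_index("predictor")
    return out.reindex(out["r"].abs().sort_values(ascending=False).index)


def split_samples(
    table: pd.DataFrame, ratio: tuple[int, int] = (4, 1), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded site-level split; the validation share is the floor fraction.

    With 170 sites and a 4:1 ratio this yields 136 modeling and 34
    validation sites; all depth rows of a site stay on the same side.
    """
    train_w, valid_w = ratio
    sites = np.sort(table["site"].unique())
    n = len(sites)
    n_valid = (n * valid_w) // (train_w + valid_w)
    if n_valid < 1 or n - n_valid < 2:
        raise ValueError(f"too few sites ({n}) for a {train_w}:{valid_w} split")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(sites)
    valid_sites = set(shuffled[:n_valid].tolist())
    is_valid = table["site"].isin(valid_sites)
    return table[~is_valid].copy(), table[is_valid].copy()


def _ols_pvalues(y, X_cols: list[np.ndarray]):
    X = sm_api.add_constant(np.column_stack(X_cols)) if X_cols else None
    model = sm_api.OLS(y, X).fit()
    return model


def fit_smlr(
    train: pd.DataFrame,
    predictors: list[str],
    depth: str = "",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> FittedModel:
    """Forward-backward stepwise linear regression on partial-F p values.

    At each forward step the candidate with the smallest coefficient p value
    enters if p < p_enter; backward steps remove the worst predictor with
    p > p_remove. For a single added coefficient the partial F test equals
    the squared t test, so coefficient p values are used. If nothing enters,
    an intercept-only model is returned and flagged.
    """
    if len(predictors) < 2:
        raise ValueError("stepwise fitting needs at least 2 candidate predictors")
    y = train["SM"].to_numpy(dtype=float)
    cols = {p: train[p].to_numpy(dtype=float) for p in predictors}
    sst = float(((y - y.mean()) ** 2).sum())
    selected: list[str] = []
    while True:
        changed = False
        if selected:
            ssr = float(_ols_pvalues(y, [cols[s] for s in selected]).ssr)
            if ssr <= 1e-12 * max(sst, 1e-12):
                break  # numerically perfect fit; further p-values are noise
        remaining = [p for p in predictors if p not in selected]
        if remaining:
            best_p, best_name = np.inf, None
            for name in remaining:
                model = _ols_pvalues(y, [cols[s] for s in selected] + [cols[name]])
                p_val = model.pvalues[-1]
                if p_val < best_p:
                    best_p, best_name = p_val, name
            if best_p < p_enter:
                selected.append(best_name)
                changed = True
        if selected:
            model = _ols_pvalues(y, [cols[s] for s in selected])
            pvals = model.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                selected.pop(worst)
                changed = True
        if not changed:
            break
    flags = []
    if not selected:
        flags.append("no predictor entered; intercept-only model")
        return FittedModel("SMLR", depth, float(np.mean(y)), {}, {}, flags)
    model = _ols_pvalues(y, [cols[s] for s in selected])
    coefs = dict(zip(selected, model.params[1:]))
    return FittedModel(
        "SMLR",
        depth,
        float(model.params[0]),
        {k: float(v) for k, v in coefs.items()},
        {"p_enter": p_enter, "p_remove": p_remove},
        flags,
    )


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def fit_ridge(
    train: pd.DataFrame,
    predictors: list[str],
    depth: str = "",
    penalty_grid=None,
    penalty: float | None = None,
    cv: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Ridge regression on internally standardized predictors.

    The penalty is chosen by k-fold cross-validated squared error over a log
    grid unless given explicitly; coefficients are returned on the original
    predictor scale, so the penalty -> 0 limit reproduces least squares.
    """
    y = train["SM"].to_numpy(dtype=float)
    X = train[list(predictors)].to_numpy(dtype=float)
    Xs, mu, sd = _standardize(X)
    flags: list[str] = []
    if penalty is None:
        if penalty_grid is None:
            penalty_grid = np.logspace(-6, 2, 25)
        folds = KFold(n_splits=min(cv, len(y)), shuffle=True, random_state=seed)
        errs = []
        for a in penalty_grid:
            sse = 0.0
            for tr, te in folds.split(Xs):
                r = Ridge(alpha=a).fit(Xs[tr], y[tr])
                sse += float(((r.predict(Xs[te]) - y[te]) ** 2).sum())
            errs.append(sse)
        penalty = float(penalty_grid[int(np.argmin(errs))])
    try:
        model = Ridge(alpha=penalty).fit(Xs, y)
    except np.linalg.LinAlgError:  # pragma: no cover - singular zero-penalty case
        penalty = float(np.min([a for a in np.atleast_1d(penalty_grid) if a > 0]))
        flags.append(f"singular design at zero penalty; used {penalty}")
        model = Ridge(alpha=penalty).fit(Xs, y)
    beta = model.coef_ / sd
    intercept = float(model.intercept_ - np.sum(beta * mu))
    return FittedModel(
        "Ridge",
        depth,
        intercept,
        {p: float(b) for p, b in zip(predictors, beta)},
        {"penalty": float(penalty)},
        flags,
    )


def fit_plsr(
    train: pd.DataFrame,
    predictors: list[str],
    depth: str = "",
    max_components: int | None = None,
    n_components: int | None = None,
    cv: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Partial least squares regression with CV-selected component count.

    With as many components as the design rank, PLSR predictions coincide
    with ordinary least squares. Coefficients are reported on the original
    scale.
    """
    y = train["SM"].to_numpy(dtype=float)
    X = train[list(predictors)].to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if max_components is None:
        max_components = rank
    if max_components < 1:
        raise ValueError("max_components must be at least 1")
    max_components = min(max_components, rank)
    if n_components is None:
        folds = KFold(n_splits=min(cv, len(y)), shuffle=True, random_state=seed)
        errs = []
        for k in range(1, max_components + 1):
            sse = 0.0
            for tr, te in folds.split(X):
                m = PLSRegression(n_components=k).fit(X[tr], y[tr])
                sse += float(((m.predict(X[te]).ravel() - y[te]) ** 2).sum())
            errs.append(sse)
        n_components = 1 + int(np.argmin(errs))
    model = PLSRegression(n_components=n_components).fit(X, y)
    beta = model.coef_.ravel()
    # predictions are y_mean + (X - x_mean) @ beta, so the raw-space intercept is:
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    return FittedModel(
        "PLSR",
        depth,
        intercept,
        {p: float(b) for p, b in zip(predictors, beta)},
        {"n_components": int(n_components)},
    )


def evaluate(
    model: FittedModel, valid: pd.DataFrame, n_train: int | None = None
) -> EvaluationReport:
    """Held-out error metrics.

    RMSE = sqrt(mean squared error), MAE = mean absolute error, MAPE = mean
    |error / measured| x 100 (undefined when a measured value is 0), R^2 =
    1 - SSE/SST, and the p value of the Pearson association between
    predictions and measurements.
    """
    if len(valid) == 0:
        raise ValueError("validation set is empty")
    measured = valid["SM"].to_numpy(dtype=float)
    predicted = model.predict(valid)
    err = predicted - measured
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.any(measured == 0):
        log.warning("MAPE undefined: validation contains zero measured values")
        mape = float("nan")
    else:
        mape = float(np.mean(np.abs(err / measured)) * 100.0)
    sst = float(np.sum((measured - measured.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else float("nan")
    if len(measured) > 2 and np.ptp(predicted) > 0 and np.ptp(measured) > 0:
        p_value = float(stats.pearsonr(measured, predicted)[1])
    else:
        p_value = float("nan")
    return EvaluationReport(
        model.method,
        model.depth,
        r2,
        rmse,
        mae,
        mape,
        p_value,
        len(valid) if n_train is None else n_train,
        len(valid),
    )


def select_model(reports: list[EvaluationReport], gates: dict = None):
    """Pick the model family by validation R^2 among gate-passing candidates.

    Gates: RMSE < 0.05, MAE < 0.02, MAPE in [0, 20)%. If no candidate
    passes, the minimum-RMSE model is returned flagged. Ties break by the
    family order SMLR < Ridge < PLSR.
    """
    if not reports:
        raise ValueError("no candidate reports")
    key_order = lambda rep: _METHOD_ORDER.get(rep.method, 99)
    passing = [r for r in reports if r.passes_gates(gates)]
    if passing:
        best = max(passing, key=lambda r: (r.r2, -key_order(r)))
        return best, []
    best = min(reports, key=lambda r: (r.rmse, key_order(r)))
    return best, ["no candidate met the error gates; fell back to min RMSE"]


def idw_surface(
    samples: pd.DataFrame,
    column: str,
    geometry: BasinGeometry,
    power: float = 2.0,
) -> RasterGrid:
    """Inverse-distance-weighted surface of a sampled soil property."""
    pts = samples.drop_duplicates("site")
    px = pts["x"].to_numpy(dtype=float)
    py = pts["y"].to_numpy(dtype=float)
    pv = pts[column].to_numpy(dtype=float)
    gx, gy = geometry.cell_centers()
    d2 = (gx[..., None] - px) ** 2 + (gy[..., None] - py) ** 2
    d = np.sqrt(d2)
    exact = d.min(axis=-1) < 1e-9
    w = 1.0 / np.maximum(d, 1e-12) ** power
    out = (w * pv).sum(axis=-1) / w.sum(axis=-1)
    if exact.any():
        nearest = d.argmin(axis=-1)
        out[exact] = pv[nearest[exact]]
    return RasterGrid(out, geometry, name=column)


def predict_raster(
    model: FittedModel,
    predictor_grids: dict[str, RasterGrid],
    clip: tuple[float, float] | None = (0.0, 1.0),
) -> RasterGrid:
    """Cellwise evaluation of a fitted linear model on predictor surfaces.

    Every retained predictor must have a grid; nodata propagates; output is
    clipped to the volumetric-fraction range by default.
    """
    missing = [p for p in model.coefficients if p not in predictor_grids]
    if missing:
        raise KeyError(f"missing predictor grids: {missing}")
    grids = [predictor_grids[p] for p in model.coefficients]
    if grids:
        geom = check_same_geometry(*grids)
    else:
        geom = next(iter(predictor_grids.values())).geometry
    out = np.full(geom.shape, model.intercept, dtype=float)
    for name, c in model.coefficients.items():
        out = out + c * predictor_grids[name].data
    if clip is not None:
        out = np.clip(out, *clip)
    return RasterGrid(out, geom, name=f"SM_{model.depth}")
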