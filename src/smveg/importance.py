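"""Gini-impurity random-forest screening of coupling-coordination drivers.

The continuous coordination degree D is discretized into its five ordinal
classes and a bootstrap forest of CART trees is grown over the eight driver
rasters. A feature's importance is the sum, over every node split on it in
every tree, of the node's Gini decrease

    gain = Gini(parent) - (n_l/n) Gini(left) - (n_r/n) Gini(right)

normalized so the shares sum to one. Child impurities are count-weighted,
the only reading that keeps every gain nonnegative. The trees themselves
are grown by scikit-learn's CART implementation; the gain accumulation is
done here by walking the fitted tree structures, because scikit-learn's
built-in importances additionally weight each gain by the node population.
A variance-impurity regression mode on raw D is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coupling import classify
from .grid import RasterGrid, check_same_frame


def gini(counts) -> float:
    """Gini impurity 1 - sum p_j^2 of a node's class counts."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty node")
    p = c / total
    return float(1.0 - (p**2).sum())


def split_gain(parent, left, right) -> float:
    """Count-weighted Gini decrease of a split; always nonnegative."""
    parent = np.asarray(parent, dtype=float)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if not np.allclose(left + right, parent):
        raise ValueError("child counts must sum to the parent counts")
    n, nl, nr = parent.sum(), left.sum(), right.sum()
    return float(gini(parent) - (nl / n) * gini(left) - (nr / n) * gini(right))


def _accumulate_tree_gains(fitted_tree, n_features: int) -> np.ndarray:
    """Per-feature impurity-decrease totals from one fitted CART tree."""
    t = fitted_tree.tree_
    gains = np.zeros(n_features)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        n = t.weighted_n_node_samples[node]
        nl = t.weighted_n_node_samples[left]
        nr = t.weighted_n_node_samples[right]
        gain = (
            t.impurity[node]
            - (nl / n) * t.impurity[left]
            - (nr / n) * t.impurity[right]
        )
        gains[t.feature[node]] += gain
    return gains


@dataclass
class ImportanceReport:
    features: list[str]
    totals: np.ndarray   # accumulated Gini decrease per feature
    shares: pd.Series    # normalized, sums to 1
    ranking: list[str]   # features by decreasing share
    mode: str
    n_trees: int


def fit_forest(
    samples: pd.DataFrame,
    features: list[str],
    label_column: str = "d_class",
    n_trees: int = 500,
    mtry: int | None = None,
    max_depth: int | None = None,
    min_leaf: int = 5,
    seed: int = 0,
    mode: str = "classification",
) -> ImportanceReport:
    """Bootstrap forest over the drivers with Gini-decrease importances.

    ``mtry`` defaults to floor(sqrt(n_features)). ``mode='regression'``
    grows variance-impurity trees on a continuous target instead.
    """
    if len(samples) < 50:
        raise ValueError("need at least 50 samples")
    X = samples[list(features)].to_numpy(dtype=float)
    y = samples[label_column].to_numpy()
    if mtry is None:
        mtry = int(np.sqrt(len(features)))
    common = dict(
        n_estimators=n_trees,
        max_features=mtry,
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    if mode == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class; importance is degenerate")
        forest = RandomForestClassifier(criterion="gini", **common)
    elif mode == "regression":
        forest = RandomForestRegressor(criterion="squared_error", **common)
    else:
        raise ValueError("mode must be 'classification' or 'regression'")
    forest.fit(X, y)
    totals = np.zeros(len(features))
    for tree in forest.estimators_:
        totals += _accumulate_tree_gains(tree, len(features))
    shares = pd.Series(totals / totals.sum(), index=list(features), name="share")
    ranking = list(shares.sort_values(ascending=False).index)
    return ImportanceReport(list(features), totals, shares, ranking, mode, n_trees)


def driver_table(
    drivers: dict[str, RasterGrid],
    d_grid: RasterGrid,
    max_pixels: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pixel driver values with the discretized D class label.

    Pixels with any missing value are dropped (so the D map may carry extra
    nodata cells relative to the drivers); a seeded random subsample bounds
    memory when the basin exceeds ``max_pixels`` cells.
    """
    check_same_frame(d_grid, *drivers.values())
    geom = d_grid.geometry
    inside = ~geom.nodata_mask
    cols = {name: g.data[inside] for name, g in drivers.items()}
    d = d_grid.data[inside]
    table = pd.DataFrame(cols)
    table["d"] = d
    table = table.dropna()
    table["d_class"] = classify(table["d"].to_numpy())
    table = table[table["d_class"] > 0]
    if len(table) > max_pixels:
        table = table.sample(n=max_pixels, random_state=seed)
    return table.reset_index(drop=True)


def rank_importance(reports: dict[str, ImportanceReport]) -> pd.DataFrame:
    """Kendall tau between the per-depth rankings; tau = 1 means identical.

    Returns the pairwise matrix with a ``consistent`` attribute-style column
    convention: the caller can check ``(out.values[triu] == 1).all()``.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare rankings")
    keys = list(reports)
    feats = reports[keys[0]].features
    for r in reports.values():
        if sorted(r.features) != sorted(feats):
            raise ValueError("reports have mismatched feature sets")
    taus = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            sa = reports[a].shares.reindex(feats)
            sb = reports[b].shares.reindex(feats)
            tau = stats.kendalltau(sa.rank(), sb.rank()).statistic
            taus.loc[a, b] = taus.loc[b, a] = tau
    return taus
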