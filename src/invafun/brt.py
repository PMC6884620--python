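"""Gaussian-loss boosted regression trees with signed relative influence.

A stagewise additive model: starting from the response mean F0, each stage
draws a bag of floor(bag_fraction * n) rows without replacement, fits a
depth-limited least-squares regression tree to the current residuals on the
bag, and updates F <- F + shrinkage * tree. Per-variable relative influence is
the percentage of total squared-error reduction attributable to splits on that
variable, and each variable's direction of effect (+/-) is the prevalent trend
of its partial-dependence curve, summarised by a density-weighted straight-line
slope (appropriate when no clear unimodal trends are present).

Split search is exhaustive over midpoints of adjacent distinct values, with
deterministic tie-breaking (first variable in column order, then the lowest
split value), so a fitted model is fully reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BRTParams",
    "TreeNode",
    "BoostedModel",
    "InfluenceTable",
    "fit_brt",
    "relative_influence",
    "partial_dependence",
    "influence_direction",
    "influence_table",
    "DEFAULT_VARIABLE_GROUPS",
]

#: Grouping of the standard environmental predictors, for influence summaries.
DEFAULT_VARIABLE_GROUPS: dict[str, str] = {
    "longitude": "geographical",
    "latitude": "geographical",
    "altitude": "geographical",
    "water_temperature": "physicochemical",
    "electrical_conductivity": "physicochemical",
    "cod": "physicochemical",
    "bod": "physicochemical",
    "tss": "physicochemical",
    "total_phosphorus": "physicochemical",
    "ammonia": "physicochemical",
    "nitrate": "physicochemical",
    "urban": "land use",
    "agricultural": "land use",
    "forest": "land use",
    "other_natural": "land use",
    "freshwater": "land use",
    "brackish_water": "land use",
}


@dataclasses.dataclass(frozen=True)
class BRTParams:
    """Boosting hyperparameters. Defaults: Gaussian loss, bag fraction 0.75,
    shrinkage 0.001; tree count and depth are configurable (10,000 stumps by
    default, the order needed for such a small learning rate)."""

    shrinkage: float = 0.001
    bag_fraction: float = 0.75
    n_trees: int = 10_000
    interaction_depth: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be non-negative")
        if self.n_trees < 0 or self.interaction_depth < 1:
            raise ValueError("n_trees >= 0 and interaction_depth >= 1 required")


@dataclasses.dataclass
class TreeNode:
    """Binary regression-tree node; leaves carry a value, internal nodes a split."""

    value: float
    var: int = -1  # -1 marks a leaf
    threshold: float = np.nan
    improvement: float = 0.0  # squared-error reduction of this split (on the bag)
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.var < 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.is_leaf:
            return np.full(X.shape[0], self.value)
        out = np.empty(X.shape[0])
        mask = X[:, self.var] <= self.threshold
        out[mask] = self.left.predict(X[mask])
        out[~mask] = self.right.predict(X[~mask])
        return out

    def walk(self):
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()


@dataclasses.dataclass
class BoostedModel:
    """Fitted ensemble: prediction = F0 + shrinkage * sum of tree outputs."""

    f0: float
    trees: list[TreeNode]
    params: BRTParams
    feature_names: list[str]
    train_X: np.ndarray
    oob_improvement: np.ndarray  # per-stage mean squared-error gain on out-of-bag rows

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = self._as_array(X)
        out = np.full(x.shape[0], self.f0)
        for tree in self.trees:
            out += self.params.shrinkage * tree.predict(x)
        return out

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


def _best_split(X: np.ndarray, r: np.ndarray) -> tuple[int, float, float] | None:
    """Exhaustive least-squares split search.

    Returns (variable index, threshold, squared-error reduction) or None when
    no split improves the fit. Reduction of a split into (L, R) is
    S_L^2/n_L + S_R^2/n_R - S^2/n with S the residual sums. Ties resolve to the
    first variable in column order, then the lowest threshold.
    """
    n, p = X.shape
    if n < 2:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    rs = r[order]
    cum = np.cumsum(rs, axis=0)
    total = cum[-1, :]
    n_left = np.arange(1, n, dtype=float)[:, None]
    s_left = cum[:-1, :]
    reduction = (
        s_left**2 / n_left
        + (total - s_left) ** 2 / (n - n_left)
        - (total**2 / n)
    )
    reduction[xs[1:] <= xs[:-1]] = -np.inf  # no cut between equal values
    best_pos = reduction.argmax(axis=0)  # first (=lowest threshold) on ties
    best_red = reduction[best_pos, np.arange(p)]
    j = int(best_red.argmax())  # first variable on ties
    if not np.isfinite(best_red[j]) or best_red[j] <= 1e-12:
        return None
    i = int(best_pos[j])
    threshold = 0.5 * (xs[i, j] + xs[i + 1, j])
    return j, float(threshold), float(best_red[j])


def _fit_tree(X: np.ndarray, r: np.ndarray, depth: int) -> TreeNode:
    node = TreeNode(value=float(r.mean()))
    if depth < 1:
        return node
    split = _best_split(X, r)
    if split is None:
        return node
    j, thr, red = split
    mask = X[:, j] <= thr
    node.var, node.threshold, node.improvement = j, thr, red
    node.left = _fit_tree(X[mask], r[mask], depth - 1)
    node.right = _fit_tree(X[~mask], r[~mask], depth - 1)
    return node


def fit_brt(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    params: BRTParams = BRTParams(),
    feature_names: Sequence[str] | None = None,
) -> BoostedModel:
    """Fit the boosted ensemble to a response (typically per-site FDis).

    ``X`` holds one row per site and one numeric column per predictor; rows
    with missing values must be removed beforehand. Deterministic given
    ``params.rng_seed``.
    """
    if isinstance(X, pd.DataFrame):
        names = list(feature_names) if feature_names is not None else list(X.columns)
        x = X[names].to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(x.shape[1])]
        )
    yv = np.asarray(y, dtype=float)
    if x.shape[0] != yv.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if np.isnan(x).any() or np.isnan(yv).any():
        raise ValueError("fit_brt: missing values in X or y; drop those rows first")
    n = x.shape[0]
    if n < 20:
        raise ValueError(f"fit_brt: need at least 20 sites, got {n}")

    f0 = float(yv.mean())
    if np.ptp(yv) == 0.0:
        warnings.warn("fit_brt: constant response; returning a zero-tree model", stacklevel=2)
        return BoostedModel(f0, [], params, names, x, np.zeros(0))

    rng = np.random.default_rng(params.rng_seed)
    n_bag = max(2, int(np.floor(params.bag_fraction * n)))
    f = np.full(n, f0)
    trees: list[TreeNode] = []
    oob_gain = np.zeros(params.n_trees)
    all_rows = np.arange(n)
    for m in range(params.n_trees):
        bag = rng.choice(n, size=n_bag, replace=False) if n_bag < n else all_rows
        resid = yv - f
        tree = _fit_tree(x[bag], resid[bag], params.interaction_depth)
        step = params.shrinkage * tree.predict(x)
        if n_bag < n:
            oob = np.setdiff1d(all_rows, bag, assume_unique=False)
            before = resid[oob] ** 2
            after = (resid[oob] - step[oob]) ** 2
            oob_gain[m] = float((before - after).mean())
        f += step
        trees.append(tree)
    return BoostedModel(f0, trees, params, names, x, oob_gain)


def relative_influence(model: BoostedModel) -> pd.Series:
    """Per-variable relative influence, as percentages summing to 100.

    The influence of a variable is the total squared-error reduction of all
    splits on it, across every tree, normalised over variables.
    """
    if not model.trees:
        raise ValueError("relative_influence: model has no trees")
    totals = np.zeros(len(model.feature_names))
    for tree in model.trees:
        for node in tree.walk():
            if not node.is_leaf:
                totals[node.var] += node.improvement
    if totals.sum() == 0:
        raise ValueError("relative_influence: no informative splits in the model")
    out = pd.Series(100.0 * totals / totals.sum(), index=model.feature_names)
    out.name = "relative_influence_pct"
    return out.sort_values(ascending=False)


def partial_dependence(
    model: BoostedModel, variable: str, n_grid: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence curve of the model on one variable.

    For each of ``n_grid`` values spanning the variable's observed range, the
    curve is the mean prediction over the training rows with that variable set
    to the grid value. Returns (grid, curve).
    """
    if variable not in model.feature_names:
        raise KeyError(f"unknown variable {variable!r}")
    j = model.feature_names.index(variable)
    col = model.train_X[:, j]
    grid = np.linspace(col.min(), col.max(), n_grid)

    using, constant = [], 0.0
    for tree in model.trees:
        if any(not nd.is_leaf and nd.var == j for nd in tree.walk()):
            using.append(tree)
        else:
            constant += model.params.shrinkage * float(tree.predict(model.train_X).mean())
    base = model.f0 + constant

    curve = np.full(n_grid, base)
    if using:
        xmod = model.train_X.copy()
        for g, v in enumerate(grid):
            xmod[:, j] = v
            curve[g] += model.params.shrinkage * sum(
                float(t.predict(xmod).mean()) for t in using
            )
    return grid, curve


def influence_direction(model: BoostedModel, variable: str, slope_tol: float = 1e-12) -> str:
    """Prevalent direction of a variable's effect: '+', '-', or '0' (flat).

    The sign of a straight line fit to the partial-dependence curve by least
    squares, weighting each grid point by the empirical density of the variable
    there, so the trend reflects where the data actually lie.
    """
    grid, curve = partial_dependence(model, variable)
    j = model.feature_names.index(variable)
    col = model.train_X[:, j]
    if np.ptp(grid) == 0:
        return "0"
    edges = np.linspace(grid[0], grid[-1], len(grid) + 1)
    counts = np.histogram(col, bins=edges)[0].astype(float)
    w = counts + 1e-9  # keep empty bins from zeroing the fit entirely
    wm_x = np.average(grid, weights=w)
    wm_y = np.average(curve, weights=w)
    slope = np.sum(w * (grid - wm_x) * (curve - wm_y)) / np.sum(w * (grid - wm_x) ** 2)
    if abs(slope) < slope_tol:
        return "0"
    return "+" if slope > 0 else "-"


class InfluenceTable(pd.DataFrame):
    """Influence summary: variable, group, relative_influence_pct, direction."""

    @property
    def _constructor(self):
        return InfluenceTable


def influence_table(
    model: BoostedModel, groups: dict[str, str] | None = None
) -> InfluenceTable:
    """Signed relative-influence summary for every predictor in the model."""
    grp = groups if groups is not None else DEFAULT_VARIABLE_GROUPS
    infl = relative_influence(model)
    rows = []
    for var, pct in infl.items():
        rows.append(
            {
                "variable": var,
                "group": grp.get(var, "other"),
                "relative_influence_pct": float(pct),
                "direction": influence_direction(model, var),
            }
        )
    return InfluenceTable(rows)
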