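"""Random-forest prediction of the (sqrt-transformed) frailty index.

A bagged ensemble of CART regression trees predicts sqrt-frailty from all
cell subpopulation concentrations plus age, CMV serostatus and measurement
date.  Bagging and out-of-bag (OOB) bookkeeping are implemented here so
that variable importance can be computed the classical way: %IncMSE, the
percentage increase in OOB mean squared error when a predictor's values
are permuted among each tree's OOB samples.  Overall performance is the
percentage of explained variance, PEV = 100 x (1 - MSE_oob / Var(y)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .frailty import analysis_set, sqrt_transform
from .phenotypes import subpopulation_names


@dataclass
class PartialDependenceCurve:
    predictors: tuple[str, ...]
    grid: tuple[np.ndarray, ...]
    values: np.ndarray            # 1-D curve or 2-D surface
    deciles: tuple[np.ndarray, ...]


@dataclass
class ForestReport:
    sex: str
    n: int
    n_trees: int
    mtry: int
    seed: int
    mse_oob: float
    response_variance: float
    pev: float
    importance: pd.DataFrame | None  # pct_inc_mse, se per predictor
    predictors: list[str]


class FrailtyForest:
    """Bagged regression forest with per-tree OOB tracking.

    Defaults follow regression-forest convention: 1000 trees, mtry = p/3,
    minimum node size 5.  Deterministic given ``seed``.
    """

    def __init__(self, n_trees: int = 1000, mtry: int | None = None,
                 min_samples_leaf: int = 5, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.trees_: list[DecisionTreeRegressor] = []
        self.oob_masks_: list[np.ndarray] = []

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        self.mtry_ = self.mtry if self.mtry is not None else max(1, p // 3)
        rng = np.random.default_rng(self.seed)
        self.trees_, self.oob_masks_ = [], []
        oob_sum = np.zeros(n)
        oob_cnt = np.zeros(n, dtype=int)
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            tree = DecisionTreeRegressor(
                max_features=self.mtry_,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(2**31)))
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
            if oob.any():
                oob_sum[oob] += tree.predict(X[oob])
                oob_cnt[oob] += 1
        self.X_, self.y_ = X, y
        seen = oob_cnt > 0
        self.oob_prediction_ = np.full(n, np.nan)
        self.oob_prediction_[seen] = oob_sum[seen] / oob_cnt[seen]
        self.mse_oob_ = float(np.mean((y[seen]
                                       - self.oob_prediction_[seen]) ** 2))
        var = float(np.var(y, ddof=1))
        self.response_variance_ = var
        self.pev_ = 100.0 * (1.0 - self.mse_oob_ / var) if var > 0 \
            else float("nan")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)


def pct_inc_mse(forest: FrailtyForest, predictors=None,
                n_repeats: int = 5, seed: int = 0,
                scale: str = "raw") -> pd.DataFrame:
    """Per-tree OOB permutation importance.

    For each repeat and each tree, the target predictor is shuffled among
    that tree's OOB samples; the OOB-aggregated predictions give a permuted
    MSE, and importance = 100 x (MSE_perm - MSE_oob) / MSE_oob.  ``scale=
    'sd'`` divides the mean raw importance by its standard error over
    repeats (the convention of some reference implementations).
    Returns a frame indexed by predictor with columns pct_inc_mse, se.
    """
    X, y = forest.X_, forest.y_
    n, p = X.shape
    idx_all = list(range(p)) if predictors is None else list(predictors)
    rng = np.random.default_rng(seed)
    imps = np.zeros((n_repeats, len(idx_all)))
    for rep in range(n_repeats):
        sums = np.zeros((len(idx_all), n))
        cnts = np.zeros(n, dtype=int)
        for tree, oob in zip(forest.trees_, forest.oob_masks_):
            k = int(oob.sum())
            if k == 0:
                continue
            rows = np.flatnonzero(oob)
            # one stacked prediction call per tree covers every predictor
            stacked = np.tile(X[rows], (len(idx_all), 1))
            for a, j in enumerate(idx_all):
                stacked[a * k:(a + 1) * k, j] = \
                    X[rows[rng.permutation(k)], j]
            pred = tree.predict(stacked)
            for a in range(len(idx_all)):
                sums[a, rows] += pred[a * k:(a + 1) * k]
            cnts[rows] += 1
        seen = cnts > 0
        for a in range(len(idx_all)):
            mse_perm = float(np.mean((y[seen] - sums[a, seen]
                                      / cnts[seen]) ** 2))
            imps[rep, a] = 100.0 * (mse_perm - forest.mse_oob_) \
                / forest.mse_oob_
    mean = imps.mean(axis=0)
    se = imps.std(axis=0, ddof=1) / np.sqrt(n_repeats) if n_repeats > 1 \
        else np.zeros(len(idx_all))
    if scale == "sd":
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = np.where(se > 0, mean / se, mean)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    return pd.DataFrame({"pct_inc_mse": mean, "se": se}, index=idx_all)


def partial_dependence(forest: FrailtyForest, X: pd.DataFrame,
                       predictors, grid_size: int = 20,
                       pct_range: tuple[float, float] = (1.0, 99.0)
                       ) -> PartialDependenceCurve:
    """Average prediction with one or two predictors fixed on a grid.

    The grid spans the central data range (default 1st-99th percentile);
    predictor deciles are returned for axis rugs.
    """
    names = [predictors] if isinstance(predictors, str) else list(predictors)
    if len(names) not in (1, 2):
        raise ValueError("partial dependence supports 1 or 2 predictors")
    cols = [X.columns.get_loc(nm) for nm in names]
    Xa = X.to_numpy(dtype=float)
    grids, deciles = [], []
    for nm in names:
        v = X[nm].to_numpy(dtype=float)
        lo, hi = np.percentile(v, pct_range)
        grids.append(np.linspace(lo, hi, grid_size))
        deciles.append(np.percentile(v, np.arange(10, 100, 10)))
    if len(names) == 1:
        stacked = np.tile(Xa, (grid_size, 1))
        for gi, gv in enumerate(grids[0]):
            stacked[gi * len(Xa):(gi + 1) * len(Xa), cols[0]] = gv
        pred = forest.predict(stacked)
        values = pred.reshape(grid_size, len(Xa)).mean(axis=1)
    else:
        values = np.empty((grid_size, grid_size))
        for gi, gv in enumerate(grids[0]):
            stacked = np.tile(Xa, (grid_size, 1))
            stacked[:, cols[0]] = gv
            for hj, hv in enumerate(grids[1]):
                stacked[hj * len(Xa):(hj + 1) * len(Xa), cols[1]] = hv
            pred = forest.predict(stacked)
            values[gi] = pred.reshape(grid_size, len(Xa)).mean(axis=1)
    return PartialDependenceCurve(tuple(names), tuple(grids), values,
                                  tuple(deciles))


def rank_importance(importance: pd.DataFrame,
                    threshold_pct: float = 50.0) -> pd.DataFrame:
    """Descending %IncMSE ranking; rows above threshold flagged.

    Ties are broken by predictor name (stable, documented).
    """
    df = importance.copy()
    df["predictor"] = df.index.astype(str)
    df = df.sort_values(["pct_inc_mse", "predictor"],
                        ascending=[False, True], kind="mergesort")
    df = df.drop(columns="predictor")
    df["flagged"] = df["pct_inc_mse"] > threshold_pct
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------

FOREST_EXTRA_PREDICTORS = ("age", "cmv_seropositive", "days_since_first_draw")


def _design_matrix(cm: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    X = cm.loc[cohort.index, [c for c in subpopulation_names()
                              if c in cm.columns]].copy()
    X["age"] = cohort["age"].astype(float)
    X["cmv_seropositive"] = (cohort["cmv_status"] == "positive").astype(float)
    draw = pd.to_datetime(cohort["blood_draw_date"])
    X["days_since_first_draw"] = (draw - draw.min()).dt.days.astype(float)
    return X


def fit_frailty_forest(cm: pd.DataFrame, cohort: pd.DataFrame,
                       sex_stratum: str, n_trees: int = 1000,
                       mtry: int | None = None, seed: int = 0,
                       importance_predictors=None,
                       importance_repeats: int = 5,
                       compute_importance: bool = True
                       ) -> tuple[ForestReport, FrailtyForest, pd.DataFrame]:
    """Fit the frailty forest for one sex stratum.

    Response is the square root of the frailty index; predictors are the
    subpopulation concentrations plus age, CMV serostatus and measurement
    date (days since the earliest blood draw).  Predictors that are
    entirely missing are dropped with a warning; remaining missing values
    are median-imputed.
    """
    sub = analysis_set(cohort)
    sub = sub[sub["sex"] == sex_stratum]
    if sub.empty:
        raise ValueError(f"no participants in sex stratum {sex_stratum!r}")
    X = _design_matrix(cm, sub)
    dead = [c for c in X.columns if X[c].isna().all()]
    if dead:
        warnings.warn(f"predictors entirely missing, dropped: {dead}",
                      stacklevel=2)
        X = X.drop(columns=dead)
    X = X.fillna(X.median())
    y = sqrt_transform(sub["frailty_index"].to_numpy(dtype=float))

    forest = FrailtyForest(n_trees=n_trees, mtry=mtry, seed=seed)
    forest.fit(X.to_numpy(dtype=float), y)
    importance = None
    if compute_importance:
        if importance_predictors is not None:
            idx = [X.columns.get_loc(nm) for nm in importance_predictors]
        else:
            idx = None
        imp = pct_inc_mse(forest, predictors=idx,
                          n_repeats=importance_repeats, seed=seed)
        imp.index = [X.columns[j] for j in imp.index]
        importance = imp
    report = ForestReport(
        sex=sex_stratum, n=len(X), n_trees=n_trees, mtry=forest.mtry_,
        seed=seed, mse_oob=forest.mse_oob_,
        response_variance=forest.response_variance_, pev=forest.pev_,
        importance=importance, predictors=list(X.columns))
    return report, forest, X
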