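"""Spatial regressions linking diversity to predictors.

All models are fitted on z-standardized response and predictors (so reported
coefficients are standardized, and for a univariate OLS the R² equals the
squared Pearson correlation). Spatial structure enters through the spatial
lag of X (SLX) model: ordinary least squares on ``[X, WX]`` where ``W`` is a
row-standardized contiguity matrix — covariate autocorrelation is absorbed by
the lagged copies while the reported effects stay the coefficients on X.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "SpatialWeights",
    "standardize",
    "pearson_screen",
    "fit_ols",
    "build_weights",
    "fit_slx",
    "stepwise_aic",
    "distance_decay",
]


@dataclass
class RegressionResult:
    """Standardized coefficients and fit statistics of one model."""

    kind: str                      # "OLS" or "SLX"
    response: str
    coef: dict[str, float]         # standardized coefficients on X (no lags)
    pvalues: dict[str, float]
    r2: float
    adj_r2: float
    aic: float
    n: int
    lag_coef: dict[str, float] = field(default_factory=dict)
    selected: list[str] | None = None

    def significant(self, alpha: float = 0.05) -> dict[str, float]:
        return {k: v for k, v in self.coef.items() if self.pvalues.get(k, 1.0) < alpha}

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "response": self.response,
            "coef": self.coef,
            "pvalues": self.pvalues,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "aic": self.aic,
            "n": self.n,
            "lag_coef": self.lag_coef,
            "selected": self.selected,
        }


@dataclass
class SpatialWeights:
    """Sparse neighbor weights over an ordered cell list."""

    matrix: sparse.csr_matrix
    scheme: str
    row_standardized: bool = True

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def lag(self, x: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(x, dtype=float)


def standardize(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Z-score the given columns (population SD); zero-variance is an error."""
    out = df.copy()
    for col in columns:
        sd = out[col].std(ddof=0)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def pearson_screen(table: pd.DataFrame, predictors, cutoff: float = 0.7):
    """Pairwise Pearson correlations with a collinearity flag.

    Returns ``(matrix, flagged)`` where ``flagged`` lists predictor pairs with
    ``|r|`` above the cutoff.
    """
    cols = list(predictors)
    data = table[cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    for col in cols:
        if data[col].std(ddof=0) == 0:
            raise ValueError(f"column {col!r} has zero variance")
    corr = data.corr(method="pearson")
    flagged = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(cols)
        for b in cols[i + 1:]
        if abs(corr.loc[a, b]) > cutoff
    ]
    return corr, flagged


def _prepare(table: pd.DataFrame, response: str, predictors, do_standardize: bool):
    cols = [response, *predictors]
    data = table[cols].dropna()
    if do_standardize:
        data = standardize(data, cols)
    return data


def _result_from_fit(fit, kind: str, response: str, predictors,
                     lag_names=(), selected=None) -> RegressionResult:
    coef = {p: float(fit.params[p]) for p in predictors}
    pvals = {p: float(fit.pvalues[p]) for p in predictors}
    lag_coef = {p: float(fit.params[p]) for p in lag_names if p in fit.params}
    return RegressionResult(
        kind=kind,
        response=response,
        coef=coef,
        pvalues=pvals,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        aic=float(fit.aic),
        n=int(fit.nobs),
        lag_coef=lag_coef,
        selected=selected,
    )


def fit_ols(table: pd.DataFrame, response: str, predictors,
            do_standardize: bool = True) -> RegressionResult:
    """OLS with intercept on standardized complete-case data."""
    predictors = list(predictors)
    data = _prepare(table, response, predictors, do_standardize)
    if len(data) <= len(predictors) + 1:
        raise ValueError("not enough complete rows for the requested model")
    X = sm.add_constant(data[predictors], has_constant="add")
    fit = sm.OLS(data[response], X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return _result_from_fit(fit, "OLS", response, predictors)


def build_weights(cells: np.ndarray, scheme: str = "queen",
                  row_standardize: bool = True) -> SpatialWeights:
    """Contiguity weights for an ordered list of (row, col) grid cells.

    ``queen`` links all 8 surrounding cells, ``rook`` the 4 orthogonal ones,
    ``knn:k`` the k nearest by center distance. Islands keep an all-zero row.
    """
    cells = np.asarray(cells, dtype=int)
    n = cells.shape[0]
    if n < 2:
        raise ValueError("need at least two cells")
    rows_idx, cols_idx, vals = [], [], []
    if scheme in ("queen", "rook"):
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        index = {(int(r), int(c)): i for i, (r, c) in enumerate(cells)}
        for i, (r, c) in enumerate(cells):
            for dr, dc in offsets:
                j = index.get((int(r) + dr, int(c) + dc))
                if j is not None:
                    rows_idx.append(i)
                    cols_idx.append(j)
                    vals.append(1.0)
    elif scheme.startswith("knn"):
        k = int(scheme.split(":", 1)[1]) if ":" in scheme else 8
        tree = cKDTree(cells.astype(float))
        _, nbrs = tree.query(cells.astype(float), k=min(k + 1, n))
        for i, row in enumerate(np.atleast_2d(nbrs)):
            for j in row:
                if j != i:
                    rows_idx.append(i)
                    cols_idx.append(int(j))
                    vals.append(1.0)
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    W = sparse.csr_matrix((vals, (rows_idx, cols_idx)), shape=(n, n))
    islands = int((W.getnnz(axis=1) == 0).sum())
    if islands:
        warnings.warn(f"build_weights: {islands} island cells with no neighbors")
    if row_standardize:
        sums = np.asarray(W.sum(axis=1)).ravel()
        sums[sums == 0] = 1.0
        W = sparse.diags(1.0 / sums) @ W
    return SpatialWeights(W.tocsr(), scheme, row_standardize)


def fit_slx(table: pd.DataFrame, response: str, predictors, W: SpatialWeights,
            do_standardize: bool = True) -> RegressionResult:
    """Spatial lag of X: OLS on each predictor plus its spatially lagged copy.

    ``W`` must be indexed to the rows of ``table``. Lag columns with zero
    variance (e.g. under an all-zero W) are dropped, so a degenerate W reduces
    SLX exactly to OLS. Reported are the standardized coefficients on X and
    the adjusted R².
    """
    predictors = list(predictors)
    if W.n != len(table):
        raise ValueError("weights are not indexed to the table rows")
    work = table.copy()
    lag_names = []
    for p in predictors:
        lagged = W.lag(work[p].to_numpy(float))
        if np.ptp(lagged[~np.isnan(lagged)]) > 0:
            name = f"lag_{p}"
            work[name] = lagged
            lag_names.append(name)
    data = _prepare(work, response, predictors + lag_names, do_standardize)
    X = sm.add_constant(data[predictors + lag_names], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient SLX design (after adding lags)")
    fit = sm.OLS(data[response], X).fit()
    return _result_from_fit(fit, "SLX", response, predictors, lag_names)


def stepwise_aic(table: pd.DataFrame, response: str, candidates,
                 do_standardize: bool = True) -> tuple[list[str], RegressionResult]:
    """Forward AIC selection from an empty model.

    At each step the candidate giving the largest AIC decrease is added;
    selection stops when no addition decreases AIC. Ties break by candidate
    list order. Returns the selected subset and its fitted model (the
    intercept-only result when nothing is selected).
    """
    candidates = list(candidates)
    data = _prepare(table, response, candidates, do_standardize)

    def aic_of(subset):
        X = sm.add_constant(data[list(subset)], has_constant="add")
        return sm.OLS(data[response], X).fit()

    selected: list[str] = []
    current = aic_of(selected)
    remaining = list(candidates)
    while remaining:
        trials = [(aic_of(selected + [c]), c) for c in remaining]
        best_fit, best_c = min(trials, key=lambda t: t[0].aic)
        if best_fit.aic < current.aic:
            selected.append(best_c)
            remaining.remove(best_c)
            current = best_fit
        else:
            break
    result = _result_from_fit(current, "OLS", response, selected, selected=list(selected))
    return selected, result


def distance_decay(table: pd.DataFrame, metric: str, distance: str = "distance_to_refugium",
                   W: SpatialWeights | None = None,
                   mask: np.ndarray | None = None) -> dict[str, RegressionResult]:
    """OLS (and SLX if weights given) of a diversity metric on refugium distance.

    ``mask`` optionally restricts rows (e.g. to contemporary forest cover);
    when set together with ``W``, the weights must already be built on the
    restricted rows.
    """
    work = table if mask is None else table.loc[np.asarray(mask, dtype=bool)]
    if len(work) == 0:
        raise ValueError("mask removes all rows")
    if work[metric].std(ddof=0) == 0:
        # a constant metric carries no decay; report a zero slope directly
        flat = RegressionResult("OLS", metric, {distance: 0.0}, {distance: 1.0},
                                0.0, 0.0, float("nan"), len(work))
        return {"OLS": flat}
    out = {"OLS": fit_ols(work, metric, [distance])}
    if W is not None:
        out["SLX"] = fit_slx(work, metric, [distance], W)
    return out
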