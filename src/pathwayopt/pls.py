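"""Single-response partial least squares (PLS1) regression.

PLS decomposes the centered predictor matrix X into orthogonal scores T and
loadings P (X = T P' + residual) and regresses the response on the first
``a`` score columns instead of on X itself, which tolerates many collinear
predictors and small n.  The implementation is the classical NIPALS
deflation algorithm for a single response; at ``a = rank(X)`` it reproduces
the OLS solution, which serves as its internal limit check.  Components are
chosen by the leave-one-out root mean squared error of prediction (RMSEP),
with centering (and optional autoscaling) recomputed inside every fold to
avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import LinlogScale, design_matrix_for_configs
from .space import LibrarySpec, PathwayConfig

__all__ = [
    "PLSFit",
    "RMSEPCurve",
    "fit_pls",
    "select_components_loo",
    "loo_r2",
    "predict_and_rank_pls",
]


@dataclass
class PLSFit:
    """A fitted PLS1 model.

    ``coef_path`` holds the regression coefficients (original predictor
    scale) for every truncation 1..n_lv, column ``a-1`` being the
    ``a``-component model; ``coefficients``/``intercept`` are the n_lv-component
    ones.  ``x_variance_pct`` / ``y_variance_pct`` are cumulative explained
    variance percentages per component count.
    """

    terms: list[str]
    n_lv: int
    n_lv_effective: int       # components actually extracted (<= n_lv)
    scores: np.ndarray        # n x a, mutually orthogonal columns
    loadings: np.ndarray      # p x a
    weights: np.ndarray       # p x a
    y_loadings: np.ndarray    # a
    coefficients: np.ndarray  # p, original scale
    intercept: float
    coef_path: np.ndarray     # p x a
    intercept_path: np.ndarray  # a
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    x_variance_pct: np.ndarray  # cumulative, length a
    y_variance_pct: np.ndarray  # cumulative, length a

    def predict(self, design: pd.DataFrame, n_lv: int | None = None) -> np.ndarray:
        a = self.n_lv if n_lv is None else n_lv
        if not 1 <= a <= self.n_lv:
            raise ValueError(f"n_lv must be in [1, {self.n_lv}]")
        X = design[self.terms].to_numpy(float)
        return self.intercept_path[a - 1] + X @ self.coef_path[:, a - 1]


def _nipals(X0: np.ndarray, y0: np.ndarray, n_lv: int, tol: float = 1e-12):
    """NIPALS deflation for one response on centered data.

    Stops early (returning the achieved component count) when the deflated
    predictor-response covariance vanishes — the response is exhausted and
    further components could only fit numerical noise.
    """
    n, p = X0.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    Xd, yd = X0.copy(), y0.copy()
    scale0 = max(float(np.linalg.norm(X0.T @ y0)), tol)
    achieved = 0
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= tol * scale0:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        achieved += 1
    return W[:, :achieved], P[:, :achieved], T[:, :achieved], q[:achieved]


def fit_pls(
    design: pd.DataFrame,
    titer,
    n_lv: int,
    autoscale: bool = False,
) -> PLSFit:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    X and y are mean-centered; with ``autoscale`` each predictor is also
    divided by its standard deviation before decomposition.  Coefficients
    are returned on the original predictor scale for every component count
    up to ``n_lv``.
    """
    y = np.asarray(titer, dtype=float)
    X = design.to_numpy(float)
    if len(y) != len(X):
        raise ValueError("titer length does not match design matrix")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    x_mean = X.mean(axis=0)
    if autoscale:
        x_scale = X.std(axis=0, ddof=1)
        if np.any(x_scale == 0):
            bad = [c for c, s in zip(design.columns, x_scale) if s == 0]
            raise ValueError(f"zero-variance columns under autoscaling: {bad}")
        x_scale = np.asarray(x_scale)
    else:
        x_scale = np.ones(X.shape[1])
    if np.all(X.std(axis=0) == 0):
        raise ValueError("design matrix has no variance")
    y_mean = float(y.mean())
    X0 = (X - x_mean) / x_scale
    y0 = y - y_mean

    W, P, T, q = _nipals(X0, y0, n_lv)
    achieved = W.shape[1]
    if achieved == 0:
        raise ValueError(
            "no extractable component: predictor-response covariance is zero"
        )

    p_dim = X.shape[1]
    coef_path = np.zeros((p_dim, n_lv))
    intercept_path = np.zeros(n_lv)
    for a in range(1, achieved + 1):
        Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
        # B = W (P'W)^-1 q, back to the original predictor scale
        b_scaled = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
        b = b_scaled / x_scale
        coef_path[:, a - 1] = b
        intercept_path[a - 1] = y_mean - float(x_mean @ b)
    # components beyond the achievable count change nothing
    for a in range(achieved, n_lv):
        coef_path[:, a] = coef_path[:, achieved - 1]
        intercept_path[a] = intercept_path[achieved - 1]

    ss_x = float(np.sum(X0**2))
    comp_x = np.array(
        [float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a])
         for a in range(achieved)]
    )
    x_var_a = 100.0 * np.cumsum(comp_x) / ss_x if ss_x > 0 else np.zeros(achieved)
    ss_y = float(np.sum(y0**2))
    y_var_a = np.zeros(achieved)
    for a in range(1, achieved + 1):
        fitted = T[:, :a] @ q[:a]
        y_var_a[a - 1] = 100.0 * (1.0 - float(np.sum((y0 - fitted) ** 2)) / ss_y) \
            if ss_y > 0 else 0.0
    x_var = np.concatenate([x_var_a, np.repeat(x_var_a[-1], n_lv - achieved)])
    y_var = np.concatenate([y_var_a, np.repeat(y_var_a[-1], n_lv - achieved)])

    return PLSFit(
        terms=list(design.columns),
        n_lv=n_lv,
        n_lv_effective=achieved,
        scores=T,
        loadings=P,
        weights=W,
        y_loadings=q,
        coefficients=coef_path[:, -1],
        intercept=float(intercept_path[-1]),
        coef_path=coef_path,
        intercept_path=intercept_path,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        x_variance_pct=x_var,
        y_variance_pct=y_var,
    )


@dataclass
class RMSEPCurve:
    """Leave-one-out RMSEP per component count (0 = fold-mean baseline)."""

    n_components: np.ndarray
    rmsep: np.ndarray
    selected: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_lv": self.n_components, "rmsep": self.rmsep})


def _loo_prediction_matrix(
    design: pd.DataFrame, y: np.ndarray, max_lv: int, autoscale: bool
) -> np.ndarray:
    """Held-out predictions for all component counts 0..max_lv.

    Entry [i, a] is the prediction of row i by the a-component model trained
    on the other rows (a = 0 is the fold mean).  One NIPALS run per fold
    yields the whole nested coefficient path.
    """
    n = len(y)
    preds = np.zeros((n, max_lv + 1))
    X = design.to_numpy(float)
    for i in range(n):
        mask = np.arange(n) != i
        fit = fit_pls(design.iloc[mask], y[mask], n_lv=max_lv, autoscale=autoscale)
        preds[i, 0] = float(y[mask].mean())
        for a in range(1, max_lv + 1):
            preds[i, a] = fit.intercept_path[a - 1] + X[i] @ fit.coef_path[:, a - 1]
    return preds


def select_components_loo(
    design: pd.DataFrame,
    titer,
    max_lv: int,
    autoscale: bool = False,
) -> RMSEPCurve:
    """Choose the number of latent variables by leave-one-out RMSEP.

    RMSEP(a) = sqrt(mean over folds of the squared held-out error of the
    a-component model); a = 0 is the fold-mean baseline.  The selected count
    is the argmin, smallest count winning ties (parsimony).
    """
    y = np.asarray(titer, dtype=float)
    if max_lv > len(y) - 2:
        raise ValueError("max_lv must be <= n - 2")
    preds = _loo_prediction_matrix(design, y, max_lv, autoscale)
    rmsep = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    selected = int(np.argmin(rmsep))  # first minimum on ties
    return RMSEPCurve(
        n_components=np.arange(max_lv + 1), rmsep=rmsep, selected=selected
    )


def loo_r2(design: pd.DataFrame, titer, n_lv: int, autoscale: bool = False) -> float:
    """Leave-one-out prediction R-squared of the ``n_lv``-component model."""
    y = np.asarray(titer, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("titer has zero variance; LOO R^2 undefined")
    preds = _loo_prediction_matrix(design, y, n_lv, autoscale)[:, n_lv]
    return 1.0 - float(np.sum((y - preds) ** 2)) / ss_tot


def predict_and_rank_pls(
    fit: PLSFit,
    space: list[PathwayConfig],
    scale: LinlogScale,
    spec: LibrarySpec,
    cds_levels: dict[str, list[str]],
    k: int = 10,
    clip_negative: bool = False,
) -> pd.DataFrame:
    """Score and rank every pathway variant with the fitted PLS model.

    Same output contract as the OLS ranker: descending predicted titer,
    ties broken by enumeration order, genotype columns plus the raw
    (optionally clipped) prediction.
    """
    full = design_matrix_for_configs(space, scale, spec, cds_levels)
    preds = fit.predict(full)
    if clip_negative:
        preds = np.maximum(preds, 0.0)
    order = np.lexsort((np.arange(len(preds)), -preds))
    rows = []
    for rank, i in enumerate(order, start=1):
        g = space[i].as_dict()
        row = {"rank": rank}
        for step, (pid, cid) in g.items():
            row[f"P_{step}"] = pid
            row[f"CDS_{step}"] = cid
        row["predicted_titer_mg_L"] = float(preds[i])
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["k"] = k
    return df
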