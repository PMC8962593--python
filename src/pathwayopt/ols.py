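"""Quadratic response-surface OLS model with backward elimination.

The titer is regressed on the design matrix of linlog promoter terms,
isozyme dummies, squares and interactions.  The initial (full) model is
pruned by backward elimination: the least significant term is removed,
respecting marginality (a main effect stays while any surviving quadratic
or interaction term contains its feature), until every remaining term is
significant at the chosen ceiling, while the model R-squared is not allowed
to drop below a floor.  Leave-one-out refits quantify predictive (rather
than descriptive) fit, and the final model scores and ranks the whole
search space.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import LinlogScale, design_matrix_for_configs
from .space import LibrarySpec, PathwayConfig

__all__ = [
    "OLSFit",
    "EliminationTrace",
    "fit_ols",
    "backward_eliminate",
    "loo_predict",
    "predict_and_rank",
    "term_features",
]

INTERCEPT = "const"


def term_features(term: str) -> set[str]:
    """Base features a design-matrix term is built from.

    'P_TAL' -> {'P_TAL'}; 'P_TAL^2' -> {'P_TAL'};
    'P_TAL:CDS_TAL' -> {'P_TAL', 'CDS_TAL'}; 'P_TAL:P_CHS' -> both.
    """
    return {re.sub(r"\^2$", "", part) for part in term.split(":")}


def is_higher_order(term: str) -> bool:
    return ":" in term or term.endswith("^2")


@dataclass
class OLSFit:
    """A fitted OLS model (intercept always included)."""

    terms: list[str]
    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    residuals: np.ndarray
    r2: float
    f_pvalue: float
    n: int
    df_resid: int

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = design[self.terms].to_numpy(float)
        beta = self.params[self.terms].to_numpy(float)
        return float(self.params[INTERCEPT]) + X @ beta


@dataclass
class EliminationTrace:
    """Audit of a backward elimination: one entry per removed term."""

    steps: list[dict] = field(default_factory=list)

    def add(self, term: str, p_at_removal: float, r2_after: float,
            model_p_after: float) -> None:
        self.steps.append(
            {
                "removed": term,
                "p_at_removal": p_at_removal,
                "r2_after": r2_after,
                "model_p_after": model_p_after,
            }
        )

    def removed_terms(self) -> list[str]:
        return [s["removed"] for s in self.steps]


def _check_design(X: np.ndarray, columns: list[str], n: int) -> None:
    # X includes the intercept column; require n > (model terms) + 1
    if n <= X.shape[1]:
        raise ValueError(
            f"n = {n} observations cannot support {X.shape[1] - 1} terms "
            f"plus intercept"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # point at the columns most entangled with the rest
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        worst = [columns[i] for i in np.argsort(-np.nanmax(np.abs(corr), axis=0))[:4]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            f"most collinear columns: {', '.join(worst)}"
        )


def fit_ols(design: pd.DataFrame, titer) -> OLSFit:
    """Least-squares fit of titer on the design-matrix columns plus intercept."""
    y = np.asarray(titer, dtype=float)
    if len(y) != len(design):
        raise ValueError("titer length does not match design matrix")
    Xc = design.to_numpy(float)
    _check_design(np.column_stack([np.ones(len(y)), Xc]),
                  [INTERCEPT] + list(design.columns), len(y))
    X = sm.add_constant(design.astype(float), has_constant="add")
    res = sm.OLS(y, X).fit()
    return OLSFit(
        terms=list(design.columns),
        params=res.params,
        pvalues=res.pvalues,
        bse=res.bse,
        residuals=np.asarray(res.resid),
        r2=float(res.rsquared),
        f_pvalue=float(res.f_pvalue) if design.shape[1] > 0 else float("nan"),
        n=int(res.nobs),
        df_resid=int(res.df_resid),
    )


def _eligible_terms(terms: list[str]) -> list[str]:
    """Terms removable under marginality.

    Higher-order terms are always eligible; a main effect only once no
    surviving higher-order term contains its feature.
    """
    protected = set()
    for t in terms:
        if is_higher_order(t):
            protected |= term_features(t)
    return [t for t in terms if is_higher_order(t) or t not in protected]


def backward_eliminate(
    design: pd.DataFrame,
    titer,
    r2_floor: float = 0.9,
    p_ceiling: float = 0.15,
) -> tuple[OLSFit, EliminationTrace]:
    """Backward elimination with marginality.

    Repeatedly removes the removal-eligible term with the largest p-value
    (ties broken toward the later column in construction order) while the
    model's R-squared stays above ``r2_floor``; stops as soon as every
    eligible term's p-value is below ``p_ceiling``, or when the next removal
    would push R-squared to or below the floor.  If even the initial model
    sits at or below the floor it is returned unpruned with a warning.
    """
    trace = EliminationTrace()
    current = design.copy()
    fit = fit_ols(current, titer)
    if fit.r2 <= r2_floor:
        warnings.warn(
            f"initial model R^2 = {fit.r2:.3f} is already <= the floor "
            f"{r2_floor}; no elimination performed",
            stacklevel=2,
        )
        return fit, trace
    while current.shape[1] > 1:
        eligible = _eligible_terms(list(current.columns))
        if not eligible:
            break
        pvals = fit.pvalues
        # later column wins ties, so iterate in reverse construction order
        order = sorted(
            eligible,
            key=lambda t: (float(pvals[t]), list(current.columns).index(t)),
        )
        worst = order[-1]
        if float(pvals[worst]) < p_ceiling:
            break
        candidate = current.drop(columns=[worst])
        cand_fit = fit_ols(candidate, titer)
        if cand_fit.r2 <= r2_floor:
            break
        trace.add(worst, float(pvals[worst]), cand_fit.r2, cand_fit.f_pvalue)
        current, fit = candidate, cand_fit
    return fit, trace


def loo_predict(
    terms: list[str], design: pd.DataFrame, titer
) -> tuple[np.ndarray, float]:
    """Leave-one-out predictions by explicit refitting.

    The model with the given terms is refit n times, each omitting one row;
    the held-out row is predicted by the reduced fit.  Returns the n
    predictions and the LOO R-squared against the observed titers.  A fold
    whose reduced design is rank deficient yields a NaN prediction and is
    excluded from the R-squared, with a warning.
    """
    y = np.asarray(titer, dtype=float)
    X = design[terms]
    n = len(y)
    if n < len(terms) + 2:
        raise ValueError(f"n = {n} too small for {len(terms)} terms plus LOO")
    preds = np.full(n, np.nan)
    bad = []
    for i in range(n):
        mask = np.arange(n) != i
        if not terms:  # intercept-only model: prediction is the fold mean
            preds[i] = float(y[mask].mean())
            continue
        try:
            fit = fit_ols(X.iloc[mask], y[mask])
        except ValueError:
            bad.append(i)
            continue
        preds[i] = fit.predict(X.iloc[[i]])[0]
    if bad:
        warnings.warn(
            f"{len(bad)} LOO fold(s) rank deficient and excluded: rows {bad}",
            stacklevel=2,
        )
    ok = ~np.isnan(preds)
    ss_res = float(np.sum((y[ok] - preds[ok]) ** 2))
    ss_tot = float(np.sum((y[ok] - y[ok].mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("titer has zero variance; LOO R^2 undefined")
    return preds, 1.0 - ss_res / ss_tot


def predict_and_rank(
    fit: OLSFit,
    space: list[PathwayConfig],
    scale: LinlogScale,
    spec: LibrarySpec,
    cds_levels: dict[str, list[str]],
    k: int = 10,
    clip_negative: bool = False,
) -> pd.DataFrame:
    """Score every pathway variant with the fitted model and rank them.

    Returns a DataFrame (one row per config, descending predicted titer,
    ties broken by enumeration order) with genotype columns and the raw
    prediction; ``rank`` 1 is best.  Predictions may be negative — the
    polynomial model family permits it — unless ``clip_negative`` asks for
    the clipped view.  ``top-k`` is just the head of the result.
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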