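"""Exploratory statistics for screening datasets.

Pairwise Pearson correlation among the continuous variables (promoter
strengths and titer) with Holm step-down multiplicity control, one-way
ANOVA per categorical pathway feature with optional Tukey HSD post-hoc
comparison, and a two-sided single-outlier Grubbs test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CorrelationReport",
    "AnovaReport",
    "GrubbsResult",
    "pearson_holm",
    "anova_oneway",
    "grubbs_test",
]


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with raw and Holm-adjusted p-values."""

    pairs: list[tuple[str, str]]
    r: dict[tuple[str, str], float]
    p_raw: dict[tuple[str, str], float]
    p_adjusted: dict[tuple[str, str], float]
    n_obs: dict[tuple[str, str], int]
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "var_a": a,
                "var_b": b,
                "r": self.r[(a, b)],
                "p_raw": self.p_raw[(a, b)],
                "p_holm": self.p_adjusted[(a, b)],
                "n": self.n_obs[(a, b)],
            }
            for a, b in self.pairs
        ]
        return pd.DataFrame(rows)


def pearson_holm(table: pd.DataFrame, min_obs: int = 3) -> CorrelationReport:
    """Pearson correlation over all column pairs, Holm-adjusted.

    Complete-case per pair (rows with a missing value in either variable
    are dropped for that pair).  The Holm family is the set of off-diagonal
    upper-triangle pairs with a defined correlation; a zero-variance
    variable makes its pairs undefined and they are flagged, not tested.
    """
    cols = list(table.columns)
    pairs_all = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    pairs, rs, ps, ns, undefined = [], {}, {}, {}, []
    for a, b in pairs_all:
        sub = table[[a, b]].dropna()
        if len(sub) < min_obs:
            raise ValueError(f"pair ({a}, {b}): need >= {min_obs} complete observations")
        xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            undefined.append((a, b))
            continue
        res = stats.pearsonr(xa, xb)
        pairs.append((a, b))
        rs[(a, b)] = float(res.statistic)
        ps[(a, b)] = float(res.pvalue)
        ns[(a, b)] = len(sub)
    if pairs:
        _rej, p_adj, _, _ = multipletests([ps[p] for p in pairs], method="holm")
        p_adjusted = {pair: float(pa) for pair, pa in zip(pairs, p_adj)}
    else:
        p_adjusted = {}
    return CorrelationReport(
        pairs=pairs, r=rs, p_raw=ps, p_adjusted=p_adjusted, n_obs=ns,
        undefined=undefined,
    )


@dataclass
class AnovaReport:
    """One-way ANOVA for one categorical feature against a response."""

    feature: str
    group_means: dict[str, float]
    group_counts: dict[str, int]
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame | None = None


def anova_oneway(
    values, groups, feature: str = "feature", tukey: bool = False
) -> AnovaReport:
    """Classic one-way ANOVA of ``values`` across the levels of ``groups``.

    Requires >= 2 groups, each non-empty, and at least one group with >= 2
    observations.  If every observation is identical the test is vacuous:
    F = 0, p = 1.  Tukey's HSD pairwise comparison is computed on request.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-D")
    levels = list(dict.fromkeys(g.tolist()))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    by_level = {lev: y[g == lev] for lev in levels}
    if not any(len(v) >= 2 for v in by_level.values()):
        raise ValueError("need at least one group with >= 2 observations")
    means = {lev: float(np.mean(v)) for lev, v in by_level.items()}
    counts = {lev: int(len(v)) for lev, v in by_level.items()}
    if np.ptp(y) == 0:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*[by_level[lev] for lev in levels])
        f_stat, p_val = float(f_stat), float(p_val)
    tukey_frame = None
    if tukey:
        res = pairwise_tukeyhsd(y, g)
        tukey_frame = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return AnovaReport(
        feature=feature,
        group_means=means,
        group_counts=counts,
        f_statistic=f_stat,
        p_value=p_val,
        tukey=tukey_frame,
    )


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of a two-sided single-outlier Grubbs test."""

    g_statistic: float
    critical_value: float
    outlier_index: int | None
    outlier_value: float | None
    alpha: float


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided, single-outlier Grubbs test.

    G = max_i |x_i - mean| / s with the sample standard deviation s
    (ddof=1).  The point of maximal deviation is flagged iff G exceeds the
    critical value

        (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)),

    where t is the upper (alpha / (2n)) quantile of Student's t with n-2
    degrees of freedom.  Non-iterative: at most one outlier is reported.
    All-equal samples have no scale, so the test is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("Grubbs test needs a 1-D sample with n >= 3")
    n = len(x)
    s = float(np.std(x, ddof=1))
    if s == 0:
        raise ValueError("all values identical: Grubbs statistic undefined (sd = 0)")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    t_crit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    critical = (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
    is_outlier = g > critical
    return GrubbsResult(
        g_statistic=g,
        critical_value=float(critical),
        outlier_index=idx if is_outlier else None,
        outlier_value=float(x[idx]) if is_outlier else None,
        alpha=alpha,
    )
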