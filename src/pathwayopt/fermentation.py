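"""Batch-fermentation kinetic parameters from time-series data.

Biomass is tracked as OD600 and converted to cell dry weight (CDW) by a
calibrated linear factor.  Over a user-chosen exponential-phase window the
specific growth rate mu is the slope of ln(CDW) versus time, the
product-on-biomass yield Y_PX is the ratio of product to biomass gained
over the window, and the specific production rate is their product,
q_p = mu * Y_PX.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FermentationSeries",
    "KineticParams",
    "od_to_cdw",
    "fit_growth_rate",
    "compute_yield_and_qp",
    "suggest_window",
]

DEFAULT_CDW_FACTOR = 0.29  # g CDW per L per OD600 unit; instrument calibration


@dataclass(frozen=True)
class FermentationSeries:
    """Sampled batch-fermentation profiles (time in h, strictly increasing)."""

    time: np.ndarray
    od600: np.ndarray
    naringenin: np.ndarray | None = None  # mg/L
    coumarate: np.ndarray | None = None   # mg/L
    glycerol: np.ndarray | None = None    # g/L

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("time series needs >= 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("od600", "naringenin", "coumarate", "glycerol"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != t.shape:
                raise ValueError(f"{name} length does not match time")
            if np.any(v < 0):
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FermentationSeries":
        def col(name):
            return df[name].to_numpy(float) if name in df.columns else None

        return cls(
            time=df["time_h"].to_numpy(float),
            od600=df["od600"].to_numpy(float),
            naringenin=col("naringenin_mg_L"),
            coumarate=col("coumarate_mg_L"),
            glycerol=col("glycerol_g_L"),
        )


@dataclass(frozen=True)
class KineticParams:
    """mu (1/h), Y_PX (mg product / g CDW), q_p (mg / g CDW / h).

    q_p = mu * Y_PX holds by construction.
    """

    mu: float
    y_px: float
    q_p: float
    window: tuple[float, float]
    cdw_factor: float
    mu_r2: float

    def __post_init__(self):
        if not np.isclose(self.q_p, self.mu * self.y_px, rtol=1e-12, atol=1e-12):
            raise ValueError("q_p must equal mu * Y_PX")


def od_to_cdw(od, factor: float = DEFAULT_CDW_FACTOR):
    """Cell dry weight (g/L) from OD600 via the linear calibration factor."""
    od_arr = np.asarray(od, dtype=float)
    if np.any(od_arr < 0):
        raise ValueError("OD600 must be >= 0")
    out = od_arr * factor
    return float(out) if np.isscalar(od) else out


def fit_growth_rate(
    series: FermentationSeries,
    window: tuple[float, float],
    factor: float = DEFAULT_CDW_FACTOR,
) -> tuple[float, dict]:
    """Exponential growth rate mu as the log-linear slope over the window.

    Least-squares slope of ln(CDW) versus time using the sample points
    inside [t_start, t_end].  Invariant to positive rescaling of CDW (a
    scale factor only shifts the intercept), so the CDW factor does not
    affect mu.  Requires >= 2 in-window points with positive biomass (with
    exactly 2 the slope is determined but carries no fit diagnostics).
    """
    t0, t1 = window
    t = np.asarray(series.time, dtype=float)
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 sample points inside the window [{t0}, {t1}]")
    cdw = od_to_cdw(np.asarray(series.od600, dtype=float)[mask], factor)
    if np.any(cdw <= 0):
        raise ValueError("non-positive CDW inside the window; cannot take log")
    res = stats.linregress(t[mask], np.log(cdw))
    return float(res.slope), {
        "r2": float(res.rvalue**2),
        "intercept": float(res.intercept),
        "n_points": int(mask.sum()),
    }


def _interp(t: np.ndarray, v: np.ndarray, at: float) -> float:
    if not (t[0] <= at <= t[-1]):
        raise ValueError(f"window endpoint {at} outside the sampled range")
    return float(np.interp(at, t, v))


def compute_yield_and_qp(
    series: FermentationSeries,
    window: tuple[float, float],
    factor: float = DEFAULT_CDW_FACTOR,
    product: str = "naringenin",
) -> KineticParams:
    """Yield and specific production rate over the window.

    Y_PX = delta(product) / delta(CDW) between the window endpoints
    (linear interpolation at non-sampled endpoints); q_p = mu * Y_PX with
    mu from the log-linear fit on the same window.  Requires biomass gain
    (delta CDW > 0) over the window.
    """
    p = getattr(series, product)
    if p is None:
        raise ValueError(f"series has no {product!r} profile")
    t = np.asarray(series.time, dtype=float)
    prod = np.asarray(p, dtype=float)
    cdw = od_to_cdw(np.asarray(series.od600, dtype=float), factor)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have t_end > t_start")
    d_p = _interp(t, prod, t1) - _interp(t, prod, t0)
    d_x = _interp(t, cdw, t1) - _interp(t, cdw, t0)
    if d_x <= 0:
        raise ValueError(f"no biomass gain over the window (delta CDW = {d_x:.4g})")
    mu, diag = fit_growth_rate(series, window, factor)
    y_px = d_p / d_x
    return KineticParams(
        mu=mu,
        y_px=y_px,
        q_p=mu * y_px,
        window=(float(t0), float(t1)),
        cdw_factor=factor,
        mu_r2=diag["r2"],
    )


def suggest_window(
    series: FermentationSeries,
    min_points: int = 4,
    factor: float = DEFAULT_CDW_FACTOR,
) -> tuple[float, float]:
    """Heuristic exponential-phase window: maximal log-linear R^2 span.

    Scans all contiguous sample spans with >= ``min_points`` points and
    positive biomass and returns the longest span whose ln(CDW) fit has the
    best R^2 (R^2 first, length as tie-break).  A convenience only — window
    choice is a judgment call and this is never applied implicitly.
    """
    t = np.asarray(series.time, dtype=float)
    cdw = od_to_cdw(np.asarray(series.od600, dtype=float), factor)
    best = None
    for i in range(len(t)):
        for j in range(i + min_points - 1, len(t)):
            seg = slice(i, j + 1)
            if np.any(cdw[seg] <= 0):
                continue
            res = stats.linregress(t[seg], np.log(cdw[seg]))
            key = (round(float(res.rvalue**2), 6), j - i)
            if best is None or key > best[0]:
                best = (key, (float(t[i]), float(t[j])))
    if best is None:
        raise ValueError("no candidate window with positive biomass")
    return best[1]
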