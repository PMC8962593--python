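"""Synthetic screening data with the statistical structure of a biosensor screen.

The generator emulates a combinatorial pathway screen end to end: a ground
truth titer landscape over genotypes (quadratic with interactions on the
linlog promoter scale, plus per-isozyme offsets and a joint high-expression
burden penalty), a transcription-factor biosensor that converts titer into
fluorescence through a Hill transfer function, plate-reader noise, and the
range-covering strain selection step that turns a colony screen into a
characterization subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .preprocess import LinlogScale, linlog_transform, scale_from_library
from .space import LibrarySpec, PathwayConfig, sample_assembly

__all__ = [
    "SyntheticLandscape",
    "HillParams",
    "SimulatedColony",
    "simulate_titer",
    "hill_response",
    "fit_hill",
    "normalize_fluorescence",
    "simulate_screen",
    "select_range_covering_subset",
]


@dataclass(frozen=True)
class SyntheticLandscape:
    """Ground-truth titer surface over pathway genotypes.

    The deterministic part is a quadratic response surface on the linlog
    promoter scale plus additive isozyme offsets; a burden penalty is
    subtracted when both TAL and CHS expression exceed ``burden_threshold``
    on the linlog scale, mimicking the joint-overexpression burden seen in
    validation strains.  Multiplicative lognormal noise with coefficient of
    variation ``noise_cv`` models biological replicate scatter; titers are
    floored at zero.  This is a statistical stand-in for the real production
    landscape, not a mechanistic model.
    """

    baseline: float
    linear_coefs: dict[str, float] = field(default_factory=dict)
    quad_coefs: dict[str, float] = field(default_factory=dict)
    interaction_coefs: dict[tuple[str, str], float] = field(default_factory=dict)
    cds_effects: dict[str, float] = field(default_factory=dict)
    burden_steps: tuple[str, str] = ("TAL", "CHS")
    burden_threshold: float = 0.6
    burden_penalty: float = 0.0
    noise_cv: float = 0.1

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.burden_penalty < 0:
            raise ValueError("burden_penalty must be >= 0")

    def mean_titer(self, config: PathwayConfig, spec: LibrarySpec,
                   scale: LinlogScale) -> float:
        """Noise-free expected titer for one genotype."""
        g = config.as_dict()
        x = {
            step: linlog_transform(spec.promoter(step, pid).tif, scale)
            for step, (pid, _cid) in g.items()
        }
        t = self.baseline
        t += sum(self.linear_coefs.get(s, 0.0) * x[s] for s in x)
        t += sum(self.quad_coefs.get(s, 0.0) * x[s] ** 2 for s in x)
        for (a, b), coef in self.interaction_coefs.items():
            t += coef * x[a] * x[b]
        for _step, (_pid, cid) in g.items():
            t += self.cds_effects.get(cid, 0.0)
        sa, sb = self.burden_steps
        if x.get(sa, -np.inf) > self.burden_threshold and \
           x.get(sb, -np.inf) > self.burden_threshold:
            t -= self.burden_penalty
        return max(0.0, t)


def simulate_titer(
    config: PathwayConfig,
    landscape: SyntheticLandscape,
    spec: LibrarySpec,
    scale: LinlogScale,
    seed: int,
) -> float:
    """Draw one noisy titer (mg/L) for a genotype; deterministic given seed."""
    mean = landscape.mean_titer(config, spec, scale)
    if landscape.noise_cv == 0:
        return mean
    rng = np.random.default_rng(seed)
    # lognormal with unit mean and the requested CV
    sigma2 = math.log(1.0 + landscape.noise_cv**2)
    factor = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2))
    return max(0.0, mean * factor)


@dataclass(frozen=True)
class HillParams:
    """Hill transfer function of a transcription-factor biosensor.

    a: basal normalized fluorescence (a.u.); M: maximal fluorescence (a.u.);
    n: Hill coefficient (cooperativity); K: half-saturation constant (mg/L).
    """

    a: float
    M: float
    n: float
    K: float

    def __post_init__(self):
        if not self.M > self.a:
            raise ValueError("need M > a (positive dynamic range)")
        if self.n <= 0 or self.K <= 0:
            raise ValueError("need n > 0 and K > 0")


def hill_response(c, p: HillParams):
    """Normalized biosensor fluorescence at ligand concentration ``c`` (mg/L).

    a + (M - a) * c^n / (K^n + c^n); strictly increasing, bounded in [a, M).
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be >= 0")
    frac = c_arr**p.n / (p.K**p.n + c_arr**p.n)
    out = p.a + (p.M - p.a) * frac
    return float(out) if np.isscalar(c) else out


def fit_hill(
    concentrations,
    fluorescence,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[HillParams, dict]:
    """Fit a Hill transfer function to a calibration curve.

    Nonlinear least squares with multiple randomized restarts (the Hill
    surface has shallow valleys in (n, K) at small sample sizes).  Returns
    the best-fit parameters and diagnostics including the residual sum of
    squares.  Requires >= 4 distinct concentrations and a detectable dynamic
    range.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if c.shape != f.shape or c.ndim != 1:
        raise ValueError("concentrations and fluorescence must be equal-length 1-D")
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.ptp(f) <= 0 or np.std(f) == 0:
        raise ValueError("no dynamic range in fluorescence; cannot fit a Hill curve")

    def model(cc, a, M, n, K):
        return a + (M - a) * cc**n / (K**n + cc**n)

    f_lo, f_hi = float(np.min(f)), float(np.max(f))
    c_pos = c[c > 0]
    k0 = float(np.median(c_pos)) if c_pos.size else 1.0
    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_restarts):
        if i == 0:
            p0 = [f_lo, f_hi, 1.0, k0]
        else:
            p0 = [
                f_lo * rng.uniform(0.5, 1.5),
                f_hi * rng.uniform(0.8, 1.5),
                rng.uniform(0.3, 4.0),
                k0 * rng.uniform(0.1, 10.0),
            ]
        try:
            popt, _ = curve_fit(
                model, c, f, p0=p0,
                bounds=([-np.inf, -np.inf, 1e-3, 1e-9], [np.inf, np.inf, 20, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(c, *popt) - f) ** 2))
        if popt[1] <= popt[0]:
            continue
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("Hill fit failed from every restart; data may be degenerate")
    popt, rss = best
    params = HillParams(a=float(popt[0]), M=float(popt[1]), n=float(popt[2]),
                        K=float(popt[3]))
    return params, {"rss": rss, "n_points": len(c)}


def normalize_fluorescence(fl, fl_blank, od, od_blank):
    """Blank-corrected fluorescence over blank-corrected optical density.

    (FL - FL_blank) / (OD600 - OD600_blank).  An OD at or below the medium
    blank means no measurable growth, so the ratio is undefined.
    """
    od_arr = np.asarray(od, dtype=float)
    if np.any(od_arr <= od_blank):
        raise ValueError("OD600 must exceed the blank (no growth detected)")
    out = (np.asarray(fl, dtype=float) - fl_blank) / (od_arr - od_blank)
    return float(out) if np.isscalar(fl) and np.isscalar(od) else out


@dataclass(frozen=True)
class SimulatedColony:
    """One screened colony: genotype, latent titer, and plate-reader readout."""

    config: PathwayConfig
    true_titer: float
    fl: float
    od: float
    fl_over_od: float


def simulate_screen(
    spec: LibrarySpec,
    landscape: SyntheticLandscape,
    hill: HillParams,
    n_colonies: int,
    seed: int,
    readout_cv: float = 0.1,
    od_mean: float = 0.8,
    od_sd: float = 0.08,
    fl_blank: float = 0.0,
    od_blank: float = 0.2,
    scale: LinlogScale | None = None,
) -> list[SimulatedColony]:
    """Simulate a biosensor-driven colony screen.

    Colonies are uniform draws from the pathway library.  Each colony's
    latent titer comes from the landscape; the biosensor converts titer to
    normalized fluorescence through the Hill curve; multiplicative Gaussian
    readout noise (CV ``readout_cv``) and a colony OD drawn from a normal
    distribution (truncated above the blank) complete the raw plate-reader
    signals, from which the blank-corrected FL/OD ratio is recomputed.
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    if scale is None:
        scale = scale_from_library(spec)
    ss = np.random.SeedSequence(seed)
    seed_cfg, seed_noise = ss.spawn(2)
    configs = sample_assembly(spec, n_colonies, seed=seed_cfg.generate_state(1)[0] % 2**31)
    rng = np.random.default_rng(seed_noise)
    out = []
    for cfg in configs:
        titer = simulate_titer(cfg, landscape, spec, scale,
                               seed=int(rng.integers(2**31)))
        od = float(rng.normal(od_mean, od_sd))
        od = max(od, od_blank + 0.05)  # a colony was picked, so it grew
        resp = hill_response(titer, hill)
        noise = 1.0 + readout_cv * float(rng.standard_normal()) if readout_cv > 0 else 1.0
        fl_over_od = max(resp * noise, 0.0)
        fl = fl_blank + fl_over_od * (od - od_blank)
        out.append(
            SimulatedColony(
                config=cfg,
                true_titer=titer,
                fl=fl,
                od=od,
                fl_over_od=normalize_fluorescence(fl, fl_blank, od, od_blank),
            )
        )
    return out


def select_range_covering_subset(
    colonies: list[SimulatedColony],
    n_select: int,
    method: str = "value",
) -> list[SimulatedColony]:
    """Pick a subset spanning the whole fluorescence range of the screen.

    Two deterministic rules are offered:

    * ``"value"`` (default): evenly spaced target levels between the maximum
      and minimum FL/OD; for each target the closest not-yet-picked colony
      is taken.  Both extremes are always included.  This spreads picks over
      the *signal* range, so a dense cluster of non-producers near basal
      fluorescence contributes only a few picks — which is what makes poor
      isozyme variants underrepresented in the characterization subset.
    * ``"rank"``: evenly spaced rank positions on the descending FL/OD
      ordering (a quantile rule); preserves pool composition.

    Deterministic; ties broken by screen order.
    """
    if n_select > len(colonies):
        raise ValueError("n_select exceeds the number of screened colonies")
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    vals = np.array([c.fl_over_od for c in colonies])
    order = sorted(range(len(colonies)), key=lambda i: (-vals[i], i))
    if n_select == 1:
        return [colonies[order[0]]]
    if method == "rank":
        positions = np.round(np.linspace(0, len(order) - 1, n_select)).astype(int)
        picks = [order[p] for p in positions]
    elif method == "value":
        targets = np.linspace(float(vals.max()), float(vals.min()), n_select)
        avail = set(range(len(colonies)))
        picks = []
        for t in targets:
            i = min(avail, key=lambda j: (abs(vals[j] - t), j))
            picks.append(i)
            avail.discard(i)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return [colonies[i] for i in picks]
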