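"""Small-network ensemble consensus prediction.

A single tiny multilayer perceptron (one log-sigmoid hidden layer with two
neurons, linear output) trained on ~30 observations will overfit in a
different way every time its weights are randomly initialized.  The
ensemble workflow turns that instability into a selection signal: many
independently initialized networks are trained by Levenberg-Marquardt (LM)
least squares, each predicts the entire genotype search space, the top-k
genotypes per network are recorded, and genotypes whose occurrence
frequency f across networks exceeds half the maximal frequency f_max form
the consensus selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import LinlogScale, linlog_transform
from .space import LibrarySpec, PathwayConfig

__all__ = [
    "AnnArchitecture",
    "AnnFit",
    "EnsembleResult",
    "encode_ann_inputs",
    "train_ann",
    "ensemble_select",
]


@dataclass(frozen=True)
class AnnArchitecture:
    """Network shape and LM training settings.

    ``damping_init`` is the initial LM damping factor lambda (the quantity
    that plays the role of a "learning rate" in LM training): it is divided
    by ``damping_down`` after an accepted step and multiplied by
    ``damping_up`` after a rejected one.
    """

    n_inputs: int
    n_hidden: int = 2
    max_epochs: int = 100
    damping_init: float = 0.01
    damping_up: float = 10.0
    damping_down: float = 10.0
    damping_max: float = 1e10
    grad_tol: float = 1e-7
    init: str = "uniform"  # "uniform" in (-0.5, 0.5) or "nguyen-widrow"

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")


def encode_ann_inputs(
    configs: list[PathwayConfig],
    scale: LinlogScale,
    spec: LibrarySpec,
    cds_levels: dict[str, list[str]],
) -> pd.DataFrame:
    """Network input matrix for a list of genotypes.

    One continuous column per step (linlog promoter strength) followed by
    one 0/1 presence column per retained isozyme level, for steps that
    retain at least two levels.  A step whose isozyme is constant after
    filtering carries no information and contributes no input neuron.
    Column order is deterministic (steps in pathway order, levels in
    declaration order).
    """
    steps = list(spec.steps)
    tif_of = {(o.step, p.id): p.tif for o in spec.operons for p in o.promoters}
    genotypes = [c.as_dict() for c in configs]
    data: dict[str, np.ndarray] = {}
    for s in steps:
        tifs = np.array([tif_of[(s, g[s][0])] for g in genotypes])
        data[f"P_{s}"] = linlog_transform(tifs, scale)
    for s in steps:
        levels = cds_levels[s]
        cids = [g[s][1] for g in genotypes]
        unknown = set(cids) - set(levels)
        if unknown:
            raise ValueError(f"unknown CDS level(s) at step {s}: {sorted(unknown)}")
        if len(levels) < 2:
            continue
        for lev in levels:
            data[f"CDS_{s}={lev}"] = np.array(
                [1.0 if cid == lev else 0.0 for cid in cids]
            )
    return pd.DataFrame(data)


def _init_weights(arch: AnnArchitecture, rng: np.random.Generator) -> np.ndarray:
    m = arch.n_hidden * (arch.n_inputs + 1) + arch.n_hidden + 1
    theta = rng.uniform(-0.5, 0.5, size=m)
    if arch.init == "nguyen-widrow":
        # rescale hidden-layer rows to the Nguyen-Widrow magnitude
        beta = 0.7 * arch.n_hidden ** (1.0 / arch.n_inputs)
        W1, b1, rest = _unpack(theta, arch)
        norms = np.linalg.norm(W1, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        W1 = beta * W1 / norms
        b1 = rng.uniform(-beta, beta, size=arch.n_hidden)
        theta = _pack(W1, b1, rest[0], rest[1])
    elif arch.init != "uniform":
        raise ValueError(f"unknown init {arch.init!r}")
    return theta


def _unpack(theta: np.ndarray, arch: AnnArchitecture):
    h, d = arch.n_hidden, arch.n_inputs
    W1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d: h * d + h]
    w2 = theta[h * d + h: h * d + 2 * h]
    b2 = theta[-1]
    return W1, b1, (w2, b2)


def _pack(W1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _forward(theta: np.ndarray, X: np.ndarray, arch: AnnArchitecture):
    W1, b1, (w2, b2) = _unpack(theta, arch)
    z = X @ W1.T + b1
    a = expit(z)
    return a @ w2 + b2, a


def _jacobian(theta: np.ndarray, X: np.ndarray, a: np.ndarray,
              arch: AnnArchitecture) -> np.ndarray:
    """d(output)/d(theta) per sample; residual Jacobian is its negative."""
    _W1, _b1, (w2, _b2) = _unpack(theta, arch)
    n = X.shape[0]
    h, d = arch.n_hidden, arch.n_inputs
    da = a * (1.0 - a) * w2  # n x h
    J = np.empty((n, h * d + 2 * h + 1))
    J[:, : h * d] = (da[:, :, None] * X[:, None, :]).reshape(n, h * d)
    J[:, h * d: h * d + h] = da
    J[:, h * d + h: h * d + 2 * h] = a
    J[:, -1] = 1.0
    return J


@dataclass
class AnnFit:
    """A trained network with its training trajectory."""

    arch: AnnArchitecture
    theta: np.ndarray
    mse_trajectory: list[float]
    converged: bool
    y_mean: float
    y_std: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out, _ = _forward(self.theta, X, self.arch)
        return self.y_mean + self.y_std * out


def train_ann(inputs, titer, arch: AnnArchitecture, seed: int) -> AnnFit:
    """Train one network by Levenberg-Marquardt least squares.

    Targets are standardized internally (and back-transformed at
    prediction).  Each epoch solves (J'J + lambda I) delta = J'e; the step
    is accepted if it lowers the sum of squared residuals (lambda shrinks)
    and rejected otherwise (lambda grows, weights unchanged).  Training
    stops at ``max_epochs``, when the gradient infinity-norm falls below
    ``grad_tol``, or when lambda overflows ``damping_max``.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(titer, dtype=float)
    if X.ndim != 2 or X.shape[1] != arch.n_inputs:
        raise ValueError(f"inputs must be n x {arch.n_inputs}")
    if len(y) != len(X) or len(y) < 4:
        raise ValueError("need matching inputs/titers with n >= 4")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    y_mean = float(y.mean())
    y_std = float(y.std())
    if y_std == 0:
        y_std = 1.0
    yt = (y - y_mean) / y_std

    rng = np.random.default_rng(seed)
    theta = _init_weights(arch, rng)
    out, a = _forward(theta, X, arch)
    e = yt - out
    sse = float(e @ e)
    traj = [sse / len(y)]
    lam = arch.damping_init
    converged = False
    eye = np.eye(len(theta))
    for _epoch in range(arch.max_epochs):
        J = _jacobian(theta, X, a, arch)  # d(out)/d(theta)
        g = J.T @ e                        # -0.5 * gradient of SSE
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient during LM training")
        if np.max(np.abs(g)) < arch.grad_tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(J.T @ J + lam * eye, g)
        except np.linalg.LinAlgError:
            lam *= arch.damping_up
            continue
        cand = theta + delta
        out_c, a_c = _forward(cand, X, arch)
        e_c = yt - out_c
        sse_c = float(e_c @ e_c)
        if not np.isfinite(sse_c):
            raise FloatingPointError("non-finite loss during LM training")
        if sse_c < sse:
            theta, out, a, e, sse = cand, out_c, a_c, e_c, sse_c
            lam /= arch.damping_down
        else:
            lam *= arch.damping_up
        traj.append(sse / len(y))
        if lam > arch.damping_max:
            converged = True
            break
    return AnnFit(
        arch=arch, theta=theta, mse_trajectory=traj, converged=converged,
        y_mean=y_mean, y_std=y_std,
    )


@dataclass
class EnsembleResult:
    """Consensus selection over many independently trained networks.

    ``frequencies`` maps a space index to the number of iterations whose
    top-k list contained that genotype; their sum is k * n_iterations.
    ``selected`` holds the indices with f strictly above the threshold
    (or >= in inclusive mode), best-first.
    """

    frequencies: dict[int, int]
    f_max: int
    threshold: float
    selected: list[int]
    mean_prediction: dict[int, float]
    n_iterations: int
    k: int
    space: list[PathwayConfig] = field(repr=False, default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for idx in self.selected:
            g = self.space[idx].as_dict() if self.space else {}
            row = {"space_index": idx}
            for step, (pid, cid) in g.items():
                row[f"P_{step}"] = pid
                row[f"CDS_{step}"] = cid
            row["f"] = self.frequencies[idx]
            row["mean_predicted_titer_mg_L"] = self.mean_prediction[idx]
            rows.append(row)
        return pd.DataFrame(rows)


def apply_frequency_threshold(
    frequencies: dict[int, int], strict: bool = True
) -> tuple[int, float, list[int]]:
    """Consensus cut: keep genotypes with f above half the maximal frequency.

    Returns (f_max, threshold, selected indices best-first).  With a strict
    (>) comparison the f_max genotype always survives, so the selection is
    never empty.
    """
    f_max = max(frequencies.values())
    threshold = 0.5 * f_max
    passing = [
        i for i, f in frequencies.items()
        if (f > threshold if strict else f >= threshold)
    ]
    passing.sort(key=lambda i: (-frequencies[i], i))
    return f_max, threshold, passing


def ensemble_select(
    train_inputs,
    titer,
    space_inputs,
    arch: AnnArchitecture,
    n_iterations: int = 1000,
    k: int = 10,
    seed: int = 0,
    strict_threshold: bool = True,
    space: list[PathwayConfig] | None = None,
) -> EnsembleResult:
    """Run the train-predict-tally ensemble and apply the 0.5 f_max cut.

    ``n_iterations`` networks are trained from independent seeded
    initializations; each predicts every genotype in ``space_inputs`` and
    its k best (ties broken by enumeration order) are tallied.  Genotypes
    with occurrence frequency strictly above 0.5 * f_max (or >= with
    ``strict_threshold=False``) are selected, ordered by descending f then
    enumeration order.  Fully reproducible from the master seed.
    """
    Xs = np.asarray(space_inputs, dtype=float)
    counts: dict[int, int] = {}
    pred_sum = np.zeros(len(Xs))
    child_seeds = np.random.SeedSequence(seed).generate_state(n_iterations) % 2**31
    for it in range(n_iterations):
        fit = train_ann(train_inputs, titer, arch, seed=int(child_seeds[it]))
        preds = fit.predict(Xs)
        pred_sum += preds
        top = np.lexsort((np.arange(len(preds)), -preds))[:k]
        for idx in top:
            counts[int(idx)] = counts.get(int(idx), 0) + 1
    f_max, threshold, passing = apply_frequency_threshold(
        counts, strict=strict_threshold
    )
    return EnsembleResult(
        frequencies=counts,
        f_max=f_max,
        threshold=threshold,
        selected=passing,
        mean_prediction={i: float(pred_sum[i] / n_iterations) for i in counts},
        n_iterations=n_iterations,
        k=k,
        space=space or [],
    )
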