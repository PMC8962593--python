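"""Screening-data preprocessing: linlog TIF transform, filtering, design matrix.

Promoter strengths span orders of magnitude, so raw TIF values are mapped to
a symmetric logarithmic scale (the "linlog" transform): the weakest library
promoter maps to -1, the strongest to +1, and the geometric midpoint to 0.
Strain records are then filtered (unsequenced genotypes; rarely observed
isozyme levels) and expanded into a quadratic response-surface design matrix
with promoter linear, dummy-coded isozyme, promoter-squared, matching
promoter-by-isozyme and promoter-by-promoter interaction columns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .space import LibrarySpec, PathwayConfig

__all__ = [
    "ScreeningRecord",
    "LinlogScale",
    "FilterReport",
    "linlog_transform",
    "scale_from_library",
    "filter_dataset",
    "build_design_matrix",
    "design_row_for_config",
]


@dataclass(frozen=True)
class ScreeningRecord:
    """One characterized strain: genotype (may be missing), readout, titer."""

    strain_id: str
    genotype: PathwayConfig | None
    titer: float
    fl_over_od: float | None = None

    def __post_init__(self):
        if self.titer is not None and not math.isnan(self.titer) and self.titer < 0:
            raise ValueError(f"strain {self.strain_id!r}: titer must be >= 0")


@dataclass(frozen=True)
class LinlogScale:
    """Endpoints of the promoter-strength scale (weakest and strongest TIF)."""

    p_min: float
    p_max: float

    def __post_init__(self):
        if not (0 < self.p_min < self.p_max):
            raise ValueError(
                f"need 0 < p_min < p_max, got p_min={self.p_min}, p_max={self.p_max}"
            )


def scale_from_library(spec: LibrarySpec) -> LinlogScale:
    """Scale spanning the weakest to strongest promoter TIF in the library."""
    tifs = [p.tif for o in spec.operons for p in o.promoters]
    return LinlogScale(p_min=min(tifs), p_max=max(tifs))


def linlog_transform(p, scale: LinlogScale):
    """Map promoter TIF(s) to the symmetric log scale.

    x = (log p - (log p_max + log p_min)/2) / ((log p_max - log p_min)/2)

    so p_min -> -1, p_max -> +1 and sqrt(p_min*p_max) -> 0.  The formula is
    log-base invariant.  Values outside [p_min, p_max] (parts from a future,
    wider library) transform fine but are flagged with a warning.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0):
        raise ValueError("promoter TIF must be positive")
    if np.any(p_arr < scale.p_min) or np.any(p_arr > scale.p_max):
        warnings.warn(
            "TIF outside the [p_min, p_max] calibration range; transforming anyway",
            stacklevel=2,
        )
    lo, hi = math.log(scale.p_min), math.log(scale.p_max)
    x = (np.log(p_arr) - (hi + lo) / 2.0) / ((hi - lo) / 2.0)
    return float(x) if np.isscalar(p) else x


@dataclass
class FilterReport:
    """Audit trail of the filtering step: every removal with its reason."""

    n_input: int = 0
    n_retained: int = 0
    removals: list[tuple[str, str]] = field(default_factory=list)  # (strain_id, reason)
    dropped_levels: dict[str, list[str]] = field(default_factory=dict)  # step -> cds ids

    def summary(self) -> str:
        lines = [f"filter: {self.n_input} records in, {self.n_retained} retained"]
        for sid, reason in self.removals:
            lines.append(f"  - removed {sid}: {reason}")
        for step, levels in self.dropped_levels.items():
            lines.append(f"  - step {step}: dropped rare level(s) {', '.join(levels)}")
        return "\n".join(lines)


def filter_dataset(
    records: list[ScreeningRecord],
    min_level_count: int = 4,
    explicit_drops: list[str] | None = None,
) -> tuple[list[ScreeningRecord], FilterReport]:
    """Apply the screening-data filtering rules.

    1. Records with a missing genotype (failed sequencing) are dropped.
    2. Records carrying any isozyme (CDS) level observed fewer than
       ``min_level_count`` times overall, or listed in ``explicit_drops``,
       are dropped.  The rationale: in an unbiased assembly, a level that is
       nearly absent from a production-ranked selection is there because it
       performs poorly, and keeping it would add model features supported by
       one or two observations.

    Returns the retained records and a report listing every removal.
    Idempotent: filtering an already-filtered dataset is a no-op.
    """
    report = FilterReport(n_input=len(records))
    explicit = set(explicit_drops or [])

    with_genotype: list[ScreeningRecord] = []
    for rec in records:
        if rec.genotype is None:
            report.removals.append((rec.strain_id, "missing genotype (sequencing failed)"))
        else:
            with_genotype.append(rec)

    counts: dict[tuple[str, str], int] = {}
    for rec in with_genotype:
        for step, (_pid, cid) in rec.genotype.assignments:
            counts[(step, cid)] = counts.get((step, cid), 0) + 1

    rare = {
        (step, cid)
        for (step, cid), n in counts.items()
        if n < min_level_count or cid in explicit
    }
    for step, cid in sorted(rare):
        report.dropped_levels.setdefault(step, []).append(cid)

    retained = []
    for rec in with_genotype:
        hit = [
            cid
            for step, (_pid, cid) in rec.genotype.assignments
            if (step, cid) in rare
        ]
        if hit:
            report.removals.append(
                (rec.strain_id, f"carries rare CDS level(s): {', '.join(hit)}")
            )
        else:
            retained.append(rec)

    report.n_retained = len(retained)
    if not retained:
        raise ValueError("filtering removed every record; relax min_level_count")
    return retained, report


def _retained_cds_levels(records: list[ScreeningRecord]) -> dict[str, list[str]]:
    """CDS levels present per step, in first-appearance order."""
    levels: dict[str, list[str]] = {}
    for rec in records:
        for step, (_pid, cid) in rec.genotype.assignments:
            levels.setdefault(step, [])
            if cid not in levels[step]:
                levels[step].append(cid)
    return levels


def _design_columns(steps: list[str], cds_levels: dict[str, list[str]]) -> list[str]:
    cols = [f"P_{s}" for s in steps]
    cols += [f"CDS_{s}" for s in steps if len(cds_levels[s]) >= 2]
    cols += [f"P_{s}^2" for s in steps]
    cols += [f"P_{s}:CDS_{s}" for s in steps if len(cds_levels[s]) >= 2]
    cols += [f"P_{a}:P_{b}" for a, b in itertools.combinations(steps, 2)]
    return cols


def _row_values(
    x: dict[str, float],
    dummy: dict[str, float],
    steps: list[str],
    cds_levels: dict[str, list[str]],
) -> list[float]:
    vals = [x[s] for s in steps]
    vals += [dummy[s] for s in steps if len(cds_levels[s]) >= 2]
    vals += [x[s] ** 2 for s in steps]
    vals += [x[s] * dummy[s] for s in steps if len(cds_levels[s]) >= 2]
    vals += [x[a] * x[b] for a, b in itertools.combinations(steps, 2)]
    return vals


def build_design_matrix(
    records: list[ScreeningRecord],
    scale: LinlogScale,
    spec: LibrarySpec,
    cds_levels: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Build the quadratic response-surface design matrix.

    Columns, in order: promoter linear terms for all steps; one 0/1 dummy
    per step that retains >= 2 isozyme levels (reference level = first CDS
    in declaration order, coded 0); promoter quadratic terms; matching
    promoter-by-isozyme interactions; all pairwise promoter-by-promoter
    interactions.  Cross-step isozyme interactions and non-matching
    promoter-by-isozyme terms are excluded as biologically subordinate.
    A step whose isozyme is constant after filtering contributes no dummy
    and no promoter-by-isozyme column.  Index = strain ids; the response is
    not a column (pass titers separately to the model fitters).
    """
    if not records:
        raise ValueError("no records")
    steps = list(spec.steps)
    if cds_levels is None:
        observed = _retained_cds_levels(records)
        # declaration order from the library keeps dummy coding stable
        cds_levels = {
            s: [c.id for c in spec.operon(s).cds_variants if c.id in observed.get(s, [])]
            for s in steps
        }
    cols = _design_columns(steps, cds_levels)
    rows = []
    index = []
    for rec in records:
        g = rec.genotype.as_dict()
        x = {s: linlog_transform(spec.promoter(s, g[s][0]).tif, scale) for s in steps}
        dummy = {}
        for s in steps:
            cid = g[s][1]
            if cid not in cds_levels[s]:
                raise ValueError(
                    f"strain {rec.strain_id!r}: CDS {cid!r} at step {s} not in the "
                    f"retained levels {cds_levels[s]}"
                )
            dummy[s] = float(cds_levels[s].index(cid)) if len(cds_levels[s]) >= 2 else 0.0
        rows.append(_row_values(x, dummy, steps, cds_levels))
        index.append(rec.strain_id)
    df = pd.DataFrame(rows, columns=cols, index=index)
    df.attrs["cds_levels"] = cds_levels
    return df


def design_matrix_for_configs(
    configs: list[PathwayConfig],
    scale: LinlogScale,
    spec: LibrarySpec,
    cds_levels: dict[str, list[str]],
) -> pd.DataFrame:
    """Design matrix for an arbitrary list of pathway variants (vectorized).

    Same column rule and ordering as :func:`build_design_matrix`; used to
    score a whole (possibly filtered) search space.  Every config must use
    only the retained CDS levels.
    """
    steps = list(spec.steps)
    tif_of = {
        (o.step, p.id): p.tif for o in spec.operons for p in o.promoters
    }
    genotypes = [c.as_dict() for c in configs]
    x = {}
    dummy = {}
    for s in steps:
        pids = [g[s][0] for g in genotypes]
        cids = [g[s][1] for g in genotypes]
        x[s] = linlog_transform(
            np.array([tif_of[(s, pid)] for pid in pids]), scale
        )
        if len(cds_levels[s]) >= 2:
            level_idx = {cid: float(i) for i, cid in enumerate(cds_levels[s])}
            try:
                dummy[s] = np.array([level_idx[cid] for cid in cids])
            except KeyError as e:
                raise ValueError(
                    f"CDS {e.args[0]!r} at step {s} not among retained levels"
                ) from None
        else:
            dummy[s] = np.zeros(len(configs))
    data = {}
    for s in steps:
        data[f"P_{s}"] = x[s]
    for s in steps:
        if len(cds_levels[s]) >= 2:
            data[f"CDS_{s}"] = dummy[s]
    for s in steps:
        data[f"P_{s}^2"] = x[s] ** 2
    for s in steps:
        if len(cds_levels[s]) >= 2:
            data[f"P_{s}:CDS_{s}"] = x[s] * dummy[s]
    for a, b in itertools.combinations(steps, 2):
        data[f"P_{a}:P_{b}"] = x[a] * x[b]
    cols = _design_columns(steps, cds_levels)
    return pd.DataFrame({c: data[c] for c in cols})


def design_row_for_config(
    config: PathwayConfig,
    scale: LinlogScale,
    spec: LibrarySpec,
    cds_levels: dict[str, list[str]],
    columns: list[str],
) -> np.ndarray:
    """Design-matrix row for an arbitrary pathway variant (for prediction)."""
    steps = list(spec.steps)
    g = config.as_dict()
    x = {s: linlog_transform(spec.promoter(s, g[s][0]).tif, scale) for s in steps}
    dummy = {}
    for s in steps:
        cid = g[s][1]
        if cid not in cds_levels[s]:
            raise ValueError(f"CDS {cid!r} at step {s} not among retained levels")
        dummy[s] = float(cds_levels[s].index(cid)) if len(cds_levels[s]) >= 2 else 0.0
    vals = _row_values(x, dummy, steps, cds_levels)
    full = dict(zip(_design_columns(steps, cds_levels), vals))
    return np.array([full[c] for c in columns])
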