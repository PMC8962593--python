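"""Combinatorial pathway genotype space.

A multi-gene pathway is assembled from interchangeable genetic parts: each
enzymatic step (operon) carries one promoter drawn from a promoter library
and one coding sequence (CDS) drawn from a set of isozyme variants.  The
genotype space is the Cartesian product of the per-operon part sets; with
10 promoters and 2 isozymes per step and four monocistronic operons it
already comprises 160,000 configurations, which is why screening covers
only a tiny fraction and model-based ranking is needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PromoterPart",
    "CdsVariant",
    "OperonSpec",
    "LibrarySpec",
    "PathwayConfig",
    "search_space_size",
    "enumerate_space",
    "sample_assembly",
    "SpaceTooLargeError",
]

DEFAULT_ENUMERATION_CAP = 10**6


class SpaceTooLargeError(ValueError):
    """Raised when full enumeration is requested for a space above the cap."""

    def __init__(self, size: int, cap: int):
        self.size = size
        self.cap = cap
        super().__init__(
            f"search space has {size} configurations, above the enumeration "
            f"cap of {cap}; raise the cap or sample instead"
        )


@dataclass(frozen=True)
class PromoterPart:
    """A promoter with a measured transcription initiation frequency (TIF).

    TIF is a fluorescence-derived promoter strength in arbitrary units;
    it must be positive because downstream transforms are logarithmic.
    """

    id: str
    tif: float

    def __post_init__(self):
        if not self.tif > 0:
            raise ValueError(f"promoter {self.id!r}: tif must be > 0, got {self.tif}")


@dataclass(frozen=True)
class CdsVariant:
    """An isozyme coding sequence for one enzymatic step (e.g. FjTAL for TAL)."""

    id: str
    step: str


@dataclass(frozen=True)
class OperonSpec:
    """Part sets available for one monocistronic operon.

    RBS and terminator counts are carried for completeness of the
    combinatorial count but default to 1 (a single fixed part per step).
    """

    step: str
    promoters: tuple[PromoterPart, ...]
    cds_variants: tuple[CdsVariant, ...]
    n_rbs: int = 1
    n_terminators: int = 1

    def __post_init__(self):
        if not self.promoters or not self.cds_variants:
            raise ValueError(f"operon {self.step!r}: part sets must be non-empty")
        if self.n_rbs < 1 or self.n_terminators < 1:
            raise ValueError(f"operon {self.step!r}: n_rbs and n_terminators must be >= 1")
        pids = [p.id for p in self.promoters]
        if len(set(pids)) != len(pids):
            raise ValueError(f"operon {self.step!r}: duplicate promoter ids")
        cids = [c.id for c in self.cds_variants]
        if len(set(cids)) != len(cids):
            raise ValueError(f"operon {self.step!r}: duplicate CDS ids")
        for c in self.cds_variants:
            if c.step != self.step:
                raise ValueError(
                    f"CDS {c.id!r} belongs to step {c.step!r}, not {self.step!r}"
                )

    @property
    def n_variants(self) -> int:
        """Number of distinct operon variants (promoters x RBS x CDS x terminators)."""
        return len(self.promoters) * self.n_rbs * len(self.cds_variants) * self.n_terminators


@dataclass(frozen=True)
class LibrarySpec:
    """Ordered list of operons defining the full pathway library."""

    operons: tuple[OperonSpec, ...]

    def __post_init__(self):
        if not self.operons:
            raise ValueError("library must have at least one operon")
        steps = [o.step for o in self.operons]
        if len(set(steps)) != len(steps):
            raise ValueError(f"duplicate step labels: {steps}")

    @property
    def steps(self) -> tuple[str, ...]:
        return tuple(o.step for o in self.operons)

    def operon(self, step: str) -> OperonSpec:
        for o in self.operons:
            if o.step == step:
                return o
        raise KeyError(f"no operon for step {step!r}")

    def promoter(self, step: str, promoter_id: str) -> PromoterPart:
        for p in self.operon(step).promoters:
            if p.id == promoter_id:
                return p
        raise KeyError(f"no promoter {promoter_id!r} at step {step!r}")


@dataclass(frozen=True)
class PathwayConfig:
    """One pathway variant: a (promoter id, CDS id) choice per step."""

    assignments: tuple[tuple[str, tuple[str, str]], ...]

    @classmethod
    def from_dict(cls, d: dict[str, tuple[str, str]]) -> "PathwayConfig":
        return cls(tuple((step, (pid, cid)) for step, (pid, cid) in d.items()))

    def as_dict(self) -> dict[str, tuple[str, str]]:
        return {step: parts for step, parts in self.assignments}

    def promoter_id(self, step: str) -> str:
        return self.as_dict()[step][0]

    def cds_id(self, step: str) -> str:
        return self.as_dict()[step][1]

    def validate(self, spec: LibrarySpec) -> None:
        d = self.as_dict()
        if set(d) != set(spec.steps):
            raise ValueError(
                f"config steps {sorted(d)} do not match library steps {sorted(spec.steps)}"
            )
        for operon in spec.operons:
            pid, cid = d[operon.step]
            if pid not in {p.id for p in operon.promoters}:
                raise ValueError(f"unknown promoter {pid!r} at step {operon.step!r}")
            if cid not in {c.id for c in operon.cds_variants}:
                raise ValueError(f"unknown CDS {cid!r} at step {operon.step!r}")


def search_space_size(spec: LibrarySpec) -> int:
    """Total number of pathway variants in the library.

    The product over operons of (#promoters x #RBSs x #CDS variants x
    #terminators).  When every operon has identical part counts this reduces
    to the familiar power form (parts per operon) ** (number of operons).
    """
    size = 1
    for operon in spec.operons:
        size *= operon.n_variants
    return size


def _operon_choices(operon: OperonSpec) -> list[tuple[str, str]]:
    # promoters outer, CDS inner, declaration order: fixed so that ranking
    # ties and top-k lists are reproducible across runs
    return [
        (p.id, c.id)
        for p in operon.promoters
        for c in operon.cds_variants
    ]


def enumerate_space(
    spec: LibrarySpec, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[PathwayConfig]:
    """Enumerate every pathway variant in deterministic lexicographic order.

    Operons vary slowest-first in pathway order; within an operon promoters
    vary before CDS variants, each in declaration order.  Refuses spaces
    above ``cap`` (full enumeration of e.g. 10**8 variants is never useful).
    """
    size = search_space_size(spec)
    if size > cap:
        raise SpaceTooLargeError(size, cap)
    steps = spec.steps
    per_operon = [_operon_choices(o) for o in spec.operons]
    return [
        PathwayConfig(tuple(zip(steps, combo)))
        for combo in itertools.product(*per_operon)
    ]


def sample_assembly(spec: LibrarySpec, n: int, seed: int) -> list[PathwayConfig]:
    """Draw ``n`` i.i.d. uniform pathway variants, as a random assembly does.

    Emulates a combinatorial one-pot assembly in which every part is equally
    likely to be integrated at its step, so colony genotypes are uniform
    over the space.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    steps = spec.steps
    per_operon = [_operon_choices(o) for o in spec.operons]
    idx = [rng.integers(len(choices), size=n) for choices in per_operon]
    return [
        PathwayConfig(
            tuple(
                (step, per_operon[j][idx[j][i]]) for j, step in enumerate(steps)
            )
        )
        for i in range(n)
    ]
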