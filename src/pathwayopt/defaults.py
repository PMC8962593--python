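"""Packaged default study conditions: library, landscape, biosensor.

The default library mirrors the structure of the screened naringenin
pathway: four monocistronic operons (TAL, 4CL, CHS, CHI), a shared library
of ten sigma-factor-specific promoters with strengths spanning orders of
magnitude, and two isozyme variants per step, giving a 160,000-variant
search space.

The promoter TIF values here are SYNTHETIC: the real library's values are
published only graphically, so a geometric series over a comparable dynamic
range (1-400 a.u.) stands in for them.  Substitute measured values via
``library_from_dict`` / the YAML config when available.  The landscape
coefficients are likewise a synthetic stand-in calibrated to the study
conditions: a 190-colony screen spanning roughly 1.5-27 mg/L, a systematic
TAL-variant effect (FjTAL > RgTAL), weak At4CL and PhCHS variants, and a
joint TAL/CHS overexpression burden.
"""

from __future__ import annotations

import numpy as np

from .simulate import HillParams, SyntheticLandscape
from .space import CdsVariant, LibrarySpec, OperonSpec, PromoterPart

__all__ = [
    "default_promoters",
    "default_library",
    "default_landscape",
    "default_hill",
    "PATHWAY_STEPS",
    "CDS_BY_STEP",
]

PATHWAY_STEPS = ("TAL", "4CL", "CHS", "CHI")

# two isozymes per step; first-listed is the dummy-coding reference level
CDS_BY_STEP = {
    "TAL": ("RgTAL", "FjTAL"),
    "4CL": ("Pc4CL", "At4CL"),
    "CHS": ("GhCHS", "PhCHS"),
    "CHI": ("MsCHI", "PhCHI"),
}


def default_promoters() -> tuple[PromoterPart, ...]:
    """Ten promoters, TIF geometric from 1 to 400 a.u. (synthetic values)."""
    tifs = np.geomspace(1.0, 400.0, 10)
    return tuple(
        PromoterPart(id=f"P_B{i + 1}", tif=float(t)) for i, t in enumerate(tifs)
    )


def default_library() -> LibrarySpec:
    """The 160,000-variant default library (10 promoters x 2 CDS per step)."""
    promoters = default_promoters()
    operons = tuple(
        OperonSpec(
            step=step,
            promoters=promoters,
            cds_variants=tuple(CdsVariant(id=c, step=step) for c in CDS_BY_STEP[step]),
        )
        for step in PATHWAY_STEPS
    )
    return LibrarySpec(operons=operons)


def default_landscape() -> SyntheticLandscape:
    """Synthetic ground-truth titer landscape (mg/L on the linlog scale).

    Qualitative structure: production rises with TAL and CHS expression and
    falls mildly with 4CL and CHI expression; curvature caps the benefit of
    extreme expression; FjTAL strongly outperforms RgTAL; At4CL and PhCHS
    are poor variants (hence their rarity among good producers); driving
    TAL and CHS both near the top of the promoter range incurs a burden
    penalty.  Coefficients are chosen so a 190-colony uniform screen spans
    roughly 1.5-27 mg/L after range-covering selection.
    """
    return SyntheticLandscape(
        baseline=11.0,
        linear_coefs={"TAL": 5.0, "4CL": -1.5, "CHS": 3.5, "CHI": -1.0},
        quad_coefs={"TAL": -1.2, "4CL": -0.4, "CHS": -0.8, "CHI": -0.4},
        interaction_coefs={("TAL", "CHS"): 1.5},
        cds_effects={
            "RgTAL": 0.0,
            "FjTAL": 7.0,
            "Pc4CL": 0.0,
            "At4CL": -14.0,
            "GhCHS": 0.0,
            "PhCHS": -14.0,
            "MsCHI": 0.0,
            "PhCHI": 1.0,
        },
        burden_steps=("TAL", "CHS"),
        burden_threshold=0.75,
        burden_penalty=8.0,
        noise_cv=0.10,
    )


def default_hill() -> HillParams:
    """Default biosensor transfer function (synthetic, plausible scale).

    Half-saturation inside the screened titer range so the sensor resolves
    producers without saturating; values are not the published fit.
    """
    return HillParams(a=120.0, M=1800.0, n=1.3, K=25.0)
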