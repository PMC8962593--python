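"""From screening records to ranked pathway designs with OLS and PLS.

The selected strains are filtered, promoter strengths go onto the linlog
scale, a quadratic-with-interactions design matrix is built, and two
regression models are trained and used to score every genotype in the
space.  The printed top design is the model's proposed next build.
"""

import numpy as np

from pathwayopt import (
    build_design_matrix,
    default_hill,
    default_landscape,
    default_library,
    filter_dataset,
    scale_from_library,
    select_range_covering_subset,
    simulate_screen,
)
from pathwayopt.io import colonies_to_records
from pathwayopt.explore import anova_oneway, grubbs_test, pearson_holm
from pathwayopt.ols import backward_eliminate, loo_predict, predict_and_rank
from pathwayopt.pls import fit_pls, loo_r2, predict_and_rank_pls, select_components_loo
from pathwayopt.space import LibrarySpec, enumerate_space

library = default_library()
scale = scale_from_library(library)
screen = simulate_screen(library, default_landscape(), default_hill(), 190, seed=1)
records = colonies_to_records(select_range_covering_subset(screen, 35))

filtered, report = filter_dataset(records)
print(report.summary())
design = build_design_matrix(filtered, scale, library)
titer = np.array([r.titer for r in filtered])
print(f"design matrix: {design.shape[0]} strains x {design.shape[1]} regressors")

# exploration: which continuous variables track titer, which isozyme wins?
import pandas as pd

cont = pd.DataFrame({f"P_{s}": design[f"P_{s}"] for s in library.steps})
cont["titer"] = titer
corr = pearson_holm(cont)
for (a, b) in corr.pairs:
    if b == "titer":
        print(f"  r({a}, titer) = {corr.r[(a, b)]:+.2f} "
              f"(Holm p = {corr.p_adjusted[(a, b)]:.3f})")
tal = anova_oneway(titer, [r.genotype.cds_id("TAL") for r in filtered],
                   feature="CDS_TAL")
print(f"  TAL isozyme ANOVA: F = {tal.f_statistic:.1f}, p = {tal.p_value:.4f}")
out = grubbs_test(titer)
print(f"  Grubbs: G = {out.g_statistic:.2f} vs {out.critical_value:.2f} -> "
      f"{'outlier at index ' + str(out.outlier_index) if out.outlier_index is not None else 'no outlier'}")

# OLS with backward elimination, then rank the filtered space
ols_fit, trace = backward_eliminate(design, titer)
_, ols_loo = loo_predict(ols_fit.terms, design, titer)
print(f"OLS: {len(ols_fit.terms)} terms survive, R2 = {ols_fit.r2:.3f}, "
      f"LOO R2 = {ols_loo:.3f}")

cds_levels = design.attrs["cds_levels"]
reduced = LibrarySpec(operons=tuple(
    type(o)(step=o.step, promoters=o.promoters,
            cds_variants=tuple(c for c in o.cds_variants
                               if c.id in cds_levels[o.step]))
    for o in library.operons
))
space = enumerate_space(reduced)
ranking = predict_and_rank(ols_fit, space, scale, library, cds_levels)
print(f"OLS best predicted design: "
      f"{ranking.iloc[0]['predicted_titer_mg_L']:.1f} mg/L")

# PLS: latent variables chosen by leave-one-out RMSEP
curve = select_components_loo(design, titer, max_lv=10)
n_lv = max(curve.selected, 1)
pls = fit_pls(design, titer, n_lv=n_lv)
print(f"PLS: {n_lv} latent variable(s); explains "
      f"{pls.y_variance_pct[-1]:.1f}% of titer variance with "
      f"{pls.x_variance_pct[-1]:.1f}% of predictor variance; "
      f"LOO R2 = {loo_r2(design, titer, n_lv):.2f}")
pls_rank = predict_and_rank_pls(pls, space, scale, library, cds_levels)
top = pls_rank.iloc[0]
print("PLS best predicted design: "
      + ", ".join(f"{s}:{top[f'P_{s}']}/{top[f'CDS_{s}']}" for s in library.steps)
      + f" -> {top['predicted_titer_mg_L']:.1f} mg/L")
# The PLS maximum is typically lower than the OLS one: PLS does not
# extrapolate the quadratic surface as aggressively.
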