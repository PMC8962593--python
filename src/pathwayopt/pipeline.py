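"""End-to-end analysis pipeline: screen -> preprocess -> explore -> model -> rank.

One master seed fans out deterministically to per-stage seeds, so a run is
byte-reproducible and each stage can also be replayed in isolation from its
intermediate files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann, explore, ols, pls
from .defaults import default_hill, default_landscape, default_library
from .io import colonies_to_records, records_to_frame
from .preprocess import (
    ScreeningRecord,
    build_design_matrix,
    filter_dataset,
    scale_from_library,
)
from .simulate import (
    HillParams,
    SyntheticLandscape,
    select_range_covering_subset,
    simulate_screen,
)
from .space import LibrarySpec, enumerate_space

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_seeds"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; every random stage has an explicit seed."""

    seed: int = 0
    n_colonies: int = 190
    n_select: int = 35
    selection_method: str = "value"
    min_level_count: int = 4
    r2_floor: float = 0.9
    p_ceiling: float = 0.15
    max_lv: int = 10
    pls_autoscale: bool = False
    ann_iterations: int = 1000
    ann_hidden: int = 2
    k: int = 10
    strict_threshold: bool = True
    enumeration_cap: int = 10**6
    outdir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


@dataclass
class RunReport:
    """Everything a run computed, each number traceable to one stage."""

    config: dict
    seeds: dict
    filter_summary: str
    n_records_in: int
    n_records_retained: int
    n_regressors: int
    n_ann_inputs: int
    space_size: int
    correlation: pd.DataFrame
    anova: dict[str, explore.AnovaReport]
    ols_fit: ols.OLSFit
    ols_trace: ols.EliminationTrace
    ols_loo_r2: float
    ols_ranking: pd.DataFrame
    rmsep_curve: pls.RMSEPCurve
    pls_fit: pls.PLSFit
    pls_loo_r2: float
    pls_ranking: pd.DataFrame
    ensemble: ann.EnsembleResult
    summary: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        s = self.summary
        lines = [
            "pathway optimization pipeline report",
            "====================================",
            f"search space size: {self.space_size}",
            f"records: {self.n_records_in} in, {self.n_records_retained} retained",
            f"design matrix: {self.n_regressors} regressors; "
            f"ANN inputs: {self.n_ann_inputs}",
            f"OLS final: {len(self.ols_fit.terms)} terms, R2 = {self.ols_fit.r2:.3f}, "
            f"model p = {self.ols_fit.f_pvalue:.3g}, LOO R2 = {self.ols_loo_r2:.3f}",
            f"OLS top prediction: {s['ols_max_pred']:.2f} mg/L",
            f"PLS: {self.pls_fit.n_lv} LV selected by LOO RMSEP; "
            f"y-variance {self.pls_fit.y_variance_pct[-1]:.2f}%, "
            f"X-variance {self.pls_fit.x_variance_pct[-1]:.2f}%, "
            f"LOO R2 = {self.pls_loo_r2:.3f}",
            f"PLS top prediction: {s['pls_max_pred']:.2f} mg/L",
            f"ANN ensemble: {self.ensemble.n_iterations} iterations, "
            f"f_max = {self.ensemble.f_max}, "
            f"{len(self.ensemble.selected)} genotype(s) above 0.5*f_max",
        ]
        return "\n".join(lines)


def stage_seeds(master: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one master seed."""
    names = ["screen", "ensemble"]
    state = np.random.SeedSequence(master).generate_state(len(names)) % 2**31
    return {name: int(s) for name, s in zip(names, state)}


def run_pipeline(
    config: PipelineConfig,
    spec: LibrarySpec | None = None,
    landscape: SyntheticLandscape | None = None,
    hill: HillParams | None = None,
    records: list[ScreeningRecord] | None = None,
) -> RunReport:
    """Run the full workflow and return the report.

    With ``records=None`` a screen is simulated under the (default or
    supplied) landscape and biosensor, and the range-covering subset is
    characterized; otherwise the given screening records are analyzed
    as-is.  Artifacts are written under ``config.outdir`` when set.
    """
    spec = spec or default_library()
    landscape = landscape or default_landscape()
    hill = hill or default_hill()
    seeds = stage_seeds(config.seed)
    scale = scale_from_library(spec)

    if records is None:
        colonies = simulate_screen(
            spec, landscape, hill, config.n_colonies, seed=seeds["screen"]
        )
        selected = select_range_covering_subset(
            colonies, config.n_select, method=config.selection_method
        )
        records = colonies_to_records(selected)

    n_in = len(records)
    filtered, report = filter_dataset(records, min_level_count=config.min_level_count)
    design = build_design_matrix(filtered, scale, spec)
    cds_levels = design.attrs["cds_levels"]
    titer = np.array([r.titer for r in filtered])

    cont = pd.DataFrame(
        {f"P_{s}": design[f"P_{s}"] for s in spec.steps} | {"titer": titer}
    )
    corr = explore.pearson_holm(cont)
    anova_reports = {}
    for s in spec.steps:
        if len(cds_levels[s]) >= 2:
            groups = [r.genotype.cds_id(s) for r in filtered]
            anova_reports[s] = explore.anova_oneway(
                titer, groups, feature=f"CDS_{s}", tukey=True
            )

    ols_fit, trace = ols.backward_eliminate(
        design, titer, r2_floor=config.r2_floor, p_ceiling=config.p_ceiling
    )
    _, ols_loo = ols.loo_predict(ols_fit.terms, design, titer)

    curve = pls.select_components_loo(
        design, titer, max_lv=min(config.max_lv, len(titer) - 2),
        autoscale=config.pls_autoscale,
    )
    n_lv = max(curve.selected, 1)
    pls_fit = pls.fit_pls(design, titer, n_lv=n_lv, autoscale=config.pls_autoscale)
    pls_loo = pls.loo_r2(design, titer, n_lv=n_lv, autoscale=config.pls_autoscale)

    # the ranked space excludes isozyme levels dropped by the filter
    reduced = LibrarySpec(
        operons=tuple(
            type(o)(
                step=o.step,
                promoters=o.promoters,
                cds_variants=tuple(
                    c for c in o.cds_variants if c.id in cds_levels[o.step]
                ),
                n_rbs=o.n_rbs,
                n_terminators=o.n_terminators,
            )
            for o in spec.operons
        )
    )
    space = enumerate_space(reduced, cap=config.enumeration_cap)
    ols_rank = ols.predict_and_rank(
        ols_fit, space, scale, spec, cds_levels, k=config.k
    )
    pls_rank = pls.predict_and_rank_pls(
        pls_fit, space, scale, spec, cds_levels, k=config.k
    )

    train_inputs = ann.encode_ann_inputs(
        [r.genotype for r in filtered], scale, spec, cds_levels
    )
    space_inputs = ann.encode_ann_inputs(space, scale, spec, cds_levels)
    arch = ann.AnnArchitecture(
        n_inputs=train_inputs.shape[1], n_hidden=config.ann_hidden
    )
    ensemble = ann.ensemble_select(
        train_inputs.to_numpy(), titer, space_inputs.to_numpy(), arch,
        n_iterations=config.ann_iterations, k=config.k,
        seed=seeds["ensemble"], strict_threshold=config.strict_threshold,
        space=space,
    )

    out = RunReport(
        config=config.to_dict(),
        seeds=seeds,
        filter_summary=report.summary(),
        n_records_in=n_in,
        n_records_retained=len(filtered),
        n_regressors=design.shape[1],
        n_ann_inputs=train_inputs.shape[1],
        space_size=len(space),
        correlation=corr.to_frame(),
        anova=anova_reports,
        ols_fit=ols_fit,
        ols_trace=trace,
        ols_loo_r2=ols_loo,
        ols_ranking=ols_rank,
        rmsep_curve=curve,
        pls_fit=pls_fit,
        pls_loo_r2=pls_loo,
        pls_ranking=pls_rank,
        ensemble=ensemble,
        summary={
            "ols_max_pred": float(ols_rank["predicted_titer_mg_L"].iloc[0]),
            "pls_max_pred": float(pls_rank["predicted_titer_mg_L"].iloc[0]),
        },
    )
    if config.outdir:
        _write_artifacts(out, filtered, design, config)
    return out


def _write_artifacts(report: RunReport, filtered, design, config: PipelineConfig):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_to_frame(filtered).to_csv(outdir / "dataset_filtered.csv", index=False)
    design.to_csv(outdir / "design_matrix.csv")
    report.correlation.to_csv(outdir / "correlation.csv", index=False)
    report.ols_ranking.head(config.k).to_csv(outdir / "ols_topk.csv", index=False)
    report.pls_ranking.head(config.k).to_csv(outdir / "pls_topk.csv", index=False)
    report.rmsep_curve.to_frame().to_csv(outdir / "rmsep_curve.csv", index=False)
    report.ensemble.to_frame().to_csv(outdir / "ensemble_selected.csv", index=False)
    coef = pd.Series(
        dict(zip(report.pls_fit.terms, report.pls_fit.coefficients)),
        name="coefficient",
    )
    coef.to_csv(outdir / "pls_coefficients.csv")
    # biplot coordinates for the first two latent variables (when present)
    fitp = report.pls_fit
    n_plot = min(2, fitp.n_lv_effective)
    pd.DataFrame(
        fitp.scores[:, :n_plot],
        columns=[f"LV{i + 1}" for i in range(n_plot)],
        index=[r.strain_id for r in filtered],
    ).to_csv(outdir / "pls_scores.csv")
    pd.DataFrame(
        fitp.loadings[:, :n_plot],
        columns=[f"LV{i + 1}" for i in range(n_plot)],
        index=fitp.terms,
    ).to_csv(outdir / "pls_loadings.csv")
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": report.config,
                "seeds": report.seeds,
                "n_records_in": report.n_records_in,
                "n_records_retained": report.n_records_retained,
                "n_regressors": report.n_regressors,
                "n_ann_inputs": report.n_ann_inputs,
                "space_size": report.space_size,
                "ols_r2": report.ols_fit.r2,
                "ols_model_p": report.ols_fit.f_pvalue,
                "ols_loo_r2": report.ols_loo_r2,
                "ols_max_pred": report.summary["ols_max_pred"],
                "pls_n_lv": report.pls_fit.n_lv,
                "pls_y_variance_pct": float(report.pls_fit.y_variance_pct[-1]),
                "pls_x_variance_pct": float(report.pls_fit.x_variance_pct[-1]),
                "pls_loo_r2": report.pls_loo_r2,
                "pls_max_pred": report.summary["pls_max_pred"],
                "ensemble_f_max": report.ensemble.f_max,
                "ensemble_n_selected": len(report.ensemble.selected),
            },
            fh,
            indent=2,
        )
    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(report.summary_text() + "\n")
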