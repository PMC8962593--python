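"""Delimited-text and YAML interfaces.

Screening datasets are comma-separated UTF-8 with a header row and "."
decimals: columns ``strain_id, P_TAL, CDS_TAL, ..., P_CHI, CDS_CHI,
fl_over_od, titer_mg_L``.  Genotype cells may be empty (failed sequencing);
the record is kept with a missing genotype.  Library specifications,
landscapes and biosensor parameters travel as YAML.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import ScreeningRecord
from .simulate import HillParams, SimulatedColony, SyntheticLandscape
from .space import CdsVariant, LibrarySpec, OperonSpec, PathwayConfig, PromoterPart

__all__ = [
    "read_screening_dataset",
    "write_screening_dataset",
    "records_from_frame",
    "records_to_frame",
    "colonies_to_records",
    "library_from_dict",
    "library_to_dict",
    "read_library",
    "write_library",
    "landscape_from_dict",
    "hill_from_dict",
    "read_fermentation_series",
]


def _genotype_columns(steps: list[str]) -> list[str]:
    cols = []
    for s in steps:
        cols += [f"P_{s}", f"CDS_{s}"]
    return cols


def _steps_from_columns(columns: list[str]) -> list[str]:
    return [c[2:] for c in columns if c.startswith("P_") and f"CDS_{c[2:]}" in columns]


def records_from_frame(df: pd.DataFrame) -> list[ScreeningRecord]:
    steps = _steps_from_columns(list(df.columns))
    if not steps:
        raise ValueError("no genotype columns (P_<step>/CDS_<step> pairs) found")
    if "titer_mg_L" not in df.columns:
        raise ValueError("missing required column titer_mg_L")
    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        cells = {}
        missing = False
        for s in steps:
            pid, cid = row[f"P_{s}"], row[f"CDS_{s}"]
            if pd.isna(pid) or pd.isna(cid) or str(pid) == "" or str(cid) == "":
                missing = True
                break
            cells[s] = (str(pid), str(cid))
        genotype = None if missing else PathwayConfig.from_dict(cells)
        titer = float(row["titer_mg_L"])
        if math.isnan(titer):
            raise ValueError(f"row {pos}: missing titer")
        if titer < 0:
            raise ValueError(f"row {pos}: negative titer {titer}")
        fl = row.get("fl_over_od", np.nan)
        records.append(
            ScreeningRecord(
                strain_id=str(row["strain_id"]) if "strain_id" in df.columns
                else f"S{pos + 1:03d}",
                genotype=genotype,
                titer=titer,
                fl_over_od=None if pd.isna(fl) else float(fl),
            )
        )
    return records


def records_to_frame(records: list[ScreeningRecord]) -> pd.DataFrame:
    steps: list[str] = []
    for rec in records:
        if rec.genotype is not None:
            steps = [s for s, _ in rec.genotype.assignments]
            break
    rows = []
    for rec in records:
        row: dict = {"strain_id": rec.strain_id}
        g = rec.genotype.as_dict() if rec.genotype is not None else {}
        for s in steps:
            pid, cid = g.get(s, ("", ""))
            row[f"P_{s}"] = pid
            row[f"CDS_{s}"] = cid
        row["fl_over_od"] = rec.fl_over_od if rec.fl_over_od is not None else ""
        row["titer_mg_L"] = rec.titer
        rows.append(row)
    return pd.DataFrame(rows)


def read_screening_dataset(path) -> list[ScreeningRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"screening dataset not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"strain_id": str})
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed dataset {path}: {e}") from e
    return records_from_frame(df)


def write_screening_dataset(records: list[ScreeningRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def colonies_to_records(colonies: list[SimulatedColony],
                        with_true_titer: bool = True) -> list[ScreeningRecord]:
    """Screening records from simulated colonies.

    The simulated latent titer plays the role of the chromatography
    measurement performed on selected strains.
    """
    return [
        ScreeningRecord(
            strain_id=f"S{i + 1:03d}",
            genotype=c.config,
            titer=c.true_titer if with_true_titer else float("nan"),
            fl_over_od=c.fl_over_od,
        )
        for i, c in enumerate(colonies)
    ]


def read_tif_table(path) -> dict[str, float]:
    """Promoter TIF table from CSV with columns promoter_id, tif."""
    df = pd.read_csv(path)
    if not {"promoter_id", "tif"} <= set(df.columns):
        raise ValueError("TIF table needs columns promoter_id, tif")
    if (df["tif"] <= 0).any():
        raise ValueError("TIF values must be positive")
    return dict(zip(df["promoter_id"].astype(str), df["tif"].astype(float)))


def write_tif_table(tifs: dict[str, float], path) -> None:
    pd.DataFrame(
        {"promoter_id": list(tifs), "tif": list(tifs.values())}
    ).to_csv(path, index=False)


def library_from_dict(d: dict) -> LibrarySpec:
    """Library from a mapping: {operons: [{step, promoters: {id: tif}, cds: [...]}]}."""
    operons = []
    for op in d["operons"]:
        step = op["step"]
        promoters = tuple(
            PromoterPart(id=pid, tif=float(tif)) for pid, tif in op["promoters"].items()
        )
        cds = tuple(CdsVariant(id=c, step=step) for c in op["cds"])
        operons.append(
            OperonSpec(
                step=step,
                promoters=promoters,
                cds_variants=cds,
                n_rbs=int(op.get("n_rbs", 1)),
                n_terminators=int(op.get("n_terminators", 1)),
            )
        )
    return LibrarySpec(operons=tuple(operons))


def library_to_dict(spec: LibrarySpec) -> dict:
    return {
        "operons": [
            {
                "step": o.step,
                "promoters": {p.id: p.tif for p in o.promoters},
                "cds": [c.id for c in o.cds_variants],
                "n_rbs": o.n_rbs,
                "n_terminators": o.n_terminators,
            }
            for o in spec.operons
        ]
    }


def read_library(path) -> LibrarySpec:
    with open(path, encoding="utf-8") as fh:
        return library_from_dict(yaml.safe_load(fh))


def write_library(spec: LibrarySpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(library_to_dict(spec), fh, sort_keys=False)


def landscape_from_dict(d: dict) -> SyntheticLandscape:
    inter = {
        tuple(k.split(":")): float(v)
        for k, v in (d.get("interaction_coefs") or {}).items()
    }
    return SyntheticLandscape(
        baseline=float(d["baseline"]),
        linear_coefs={k: float(v) for k, v in (d.get("linear_coefs") or {}).items()},
        quad_coefs={k: float(v) for k, v in (d.get("quad_coefs") or {}).items()},
        interaction_coefs=inter,
        cds_effects={k: float(v) for k, v in (d.get("cds_effects") or {}).items()},
        burden_steps=tuple(d.get("burden_steps", ("TAL", "CHS"))),
        burden_threshold=float(d.get("burden_threshold", 0.6)),
        burden_penalty=float(d.get("burden_penalty", 0.0)),
        noise_cv=float(d.get("noise_cv", 0.1)),
    )


def hill_from_dict(d: dict) -> HillParams:
    return HillParams(a=float(d["a"]), M=float(d["M"]), n=float(d["n"]),
                      K=float(d["K"]))


def read_fermentation_series(path):
    from .fermentation import FermentationSeries

    df = pd.read_csv(path)
    return FermentationSeries.from_frame(df)
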