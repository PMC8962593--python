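import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathwayopt.preprocess import (
    LinlogScale,
    ScreeningRecord,
    build_design_matrix,
    design_matrix_for_configs,
    filter_dataset,
    linlog_transform,
)
from pathwayopt.space import PathwayConfig, sample_assembly

from conftest import CDS, make_library


def make_records(library, n, seed=0, titers=None, cds_override=None):
    configs = sample_assembly(library, n, seed=seed)
    records = []
    for i, cfg in enumerate(configs):
        if cds_override:
            d = cfg.as_dict()
            for step, cid in cds_override(i):
                d[step] = (d[step][0], cid)
            cfg = PathwayConfig.from_dict(d)
        records.append(
            ScreeningRecord(
                strain_id=f"S{i:03d}",
                genotype=cfg,
                titer=float(titers[i]) if titers is not None else float(i + 1),
            )
        )
    return records


class TestLinlog:
    def test_endpoints_and_geometric_midpoint(self):
        s = LinlogScale(p_min=2.0, p_max=800.0)
        assert linlog_transform(2.0, s) == pytest.approx(-1.0)
        assert linlog_transform(800.0, s) == pytest.approx(1.0)
        assert linlog_transform(math.sqrt(2.0 * 800.0), s) == pytest.approx(0.0)

    def test_non_positive_tif_rejected(self):
        s = LinlogScale(1.0, 10.0)
        with pytest.raises(ValueError):
            linlog_transform(0.0, s)

    def test_out_of_range_warns_but_transforms(self):
        s = LinlogScale(1.0, 10.0)
        with pytest.warns(UserWarning):
            x = linlog_transform(100.0, s)
        assert x > 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        p_min=st.floats(1e-3, 1e3),
        ratio=st.floats(1.5, 1e6),
        frac=st.floats(0.0, 1.0),
    )
    def test_base_invariance_and_monotonicity(self, p_min, ratio, frac):
        p_max = p_min * ratio
        s = LinlogScale(p_min, p_max)
        p = p_min * ratio**frac
        x = linlog_transform(p, s)
        # closed form in any log base: 2*log_b(p/pmin)/log_b(pmax/pmin) - 1
        expected = 2 * math.log10(p / p_min) / math.log10(p_max / p_min) - 1
        assert x == pytest.approx(expected, abs=1e-9)
        if frac < 0.99:
            assert linlog_transform(p * ratio**0.01, s) > x


class TestFilterDataset:
    def test_counting_oracle_rare_level(self, library):
        # 20 rows, one CDS level appearing exactly twice -> those 2 rows out
        records = make_records(
            library, 20, seed=1,
            cds_override=lambda i: [("TAL", "FjTAL" if i >= 2 else "RgTAL")],
        )
        filtered, report = filter_dataset(records, min_level_count=3)
        assert len(filtered) == 18
        assert [sid for sid, _ in report.removals] == ["S000", "S001"]
        assert report.dropped_levels == {"TAL": ["RgTAL"]}

    def test_all_levels_abundant_is_noop(self, library):
        records = make_records(
            library, 24, seed=2,
            cds_override=lambda i: [
                (step, CDS[step][i % 2]) for step in library.steps
            ],
        )
        filtered, report = filter_dataset(records, min_level_count=4)
        assert filtered == records
        assert report.removals == []

    def test_missing_genotype_dropped(self, library):
        records = make_records(library, 10, seed=3)
        records[4] = ScreeningRecord("S004", None, titer=3.0)
        filtered, report = filter_dataset(records, min_level_count=1)
        assert len(filtered) == 9
        assert report.removals[0][0] == "S004"
        assert "genotype" in report.removals[0][1]

    def test_idempotent(self, library):
        records = make_records(library, 30, seed=4)
        once, _ = filter_dataset(records)
        twice, rep = filter_dataset(once)
        assert twice == once and rep.removals == []

    def test_explicit_drop_overrides_counts(self, library):
        records = make_records(
            library, 24, seed=5,
            cds_override=lambda i: [
                (step, CDS[step][i % 2]) for step in library.steps
            ],
        )
        filtered, report = filter_dataset(records, explicit_drops=["At4CL"])
        assert all(r.genotype.cds_id("4CL") == "Pc4CL" for r in filtered)
        assert report.dropped_levels.get("4CL") == ["At4CL"]

    def test_everything_removed_is_an_error(self, library):
        records = make_records(library, 3, seed=6)
        with pytest.raises(ValueError, match="every record"):
            filter_dataset(records, min_level_count=10)


class TestDesignMatrix:
    def assert_columns(self, library, scale, cds_levels, expected):
        records = make_records(library, 30, seed=7)
        # restrict genotypes to the given retained levels
        fixed = []
        for r in records:
            d = r.genotype.as_dict()
            for step, levels in cds_levels.items():
                if d[step][1] not in levels:
                    d[step] = (d[step][0], levels[0])
            fixed.append(
                ScreeningRecord(r.strain_id, PathwayConfig.from_dict(d), r.titer)
            )
        design = build_design_matrix(fixed, scale, library, cds_levels=cds_levels)
        assert design.shape[1] == expected
        return design

    def test_two_level_tal_chi_single_level_4cl_chs_gives_18(self, library, scale):
        cds_levels = {
            "TAL": ["RgTAL", "FjTAL"],
            "4CL": ["Pc4CL"],
            "CHS": ["GhCHS"],
            "CHI": ["MsCHI", "PhCHI"],
        }
        design = self.assert_columns(library, scale, cds_levels, 18)
        assert list(design.columns[:6]) == [
            "P_TAL", "P_4CL", "P_CHS", "P_CHI", "CDS_TAL", "CDS_CHI",
        ]

    def test_all_single_level_gives_14(self, library, scale):
        cds_levels = {s: [CDS[s][0]] for s in library.steps}
        self.assert_columns(library, scale, cds_levels, 14)

    def test_all_two_level_gives_22(self, library, scale):
        cds_levels = {s: list(CDS[s]) for s in library.steps}
        self.assert_columns(library, scale, cds_levels, 22)

    def test_interaction_columns_are_products(self, library, scale):
        records = make_records(library, 25, seed=8)
        design = build_design_matrix(records, scale, library)
        for a, b in [("TAL", "4CL"), ("CHS", "CHI"), ("TAL", "CHI")]:
            np.testing.assert_allclose(
                design[f"P_{a}:P_{b}"], design[f"P_{a}"] * design[f"P_{b}"]
            )
        for s in library.steps:
            np.testing.assert_allclose(design[f"P_{s}^2"], design[f"P_{s}"] ** 2)
            if f"CDS_{s}" in design.columns:
                np.testing.assert_allclose(
                    design[f"P_{s}:CDS_{s}"], design[f"P_{s}"] * design[f"CDS_{s}"]
                )

    def test_dummy_reference_is_first_declared_level(self, library, scale):
        records = make_records(library, 25, seed=9)
        design = build_design_matrix(records, scale, library)
        for s in library.steps:
            if f"CDS_{s}" not in design.columns:
                continue
            ref = CDS[s][0]
            for r in records:
                expected = 0.0 if r.genotype.cds_id(s) == ref else 1.0
                assert design.loc[r.strain_id, f"CDS_{s}"] == expected

    def test_config_matrix_agrees_with_record_matrix(self, library, scale):
        records = make_records(library, 15, seed=10)
        design = build_design_matrix(records, scale, library)
        cds_levels = design.attrs["cds_levels"]
        configs = [r.genotype for r in records]
        other = design_matrix_for_configs(configs, scale, library, cds_levels)
        np.testing.assert_allclose(design.to_numpy(), other.to_numpy())
        assert list(design.columns) == list(other.columns)
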