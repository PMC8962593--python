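import numpy as np
import pandas as pd
import pytest

from pathwayopt.ols import (
    backward_eliminate,
    fit_ols,
    loo_predict,
    predict_and_rank,
    term_features,
)
from pathwayopt.preprocess import build_design_matrix
from pathwayopt.space import enumerate_space

from conftest import make_library
from test_preprocess import make_records


def random_design(n, p, seed, columns=None):
    rng = np.random.default_rng(seed)
    cols = columns or [f"x{i}" for i in range(p)]
    return pd.DataFrame(rng.normal(size=(n, p)), columns=cols)


class TestFitOls:
    def test_exact_linear_data_r2_one(self):
        X = random_design(12, 3, 0)
        y = 4.0 * X["x1"] + 2.0
        fit = fit_ols(X, y)
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)
        assert fit.params["x1"] == pytest.approx(4.0)
        assert fit.params["const"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        X = random_design(10, 3, seed)
        rng = np.random.default_rng(100 + seed)
        y = rng.normal(size=10)
        fit = fit_ols(X, y)
        Xa = np.column_stack([np.ones(10), X.to_numpy()])
        beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
        np.testing.assert_allclose(
            np.r_[fit.params["const"], fit.params[fit.terms]], beta, atol=1e-10
        )

    def test_residuals_sum_to_zero_with_intercept(self):
        X = random_design(15, 4, 2)
        y = np.random.default_rng(3).normal(size=15)
        fit = fit_ols(X, y)
        assert abs(fit.residuals.sum()) < 1e-9

    def test_rank_deficiency_reported_with_columns(self):
        X = random_design(12, 2, 4)
        X["dup"] = X["x0"] * 2.0
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(X, np.arange(12.0))

    def test_too_few_observations_rejected(self):
        X = random_design(4, 4, 5)
        with pytest.raises(ValueError, match="observations"):
            fit_ols(X, np.arange(4.0))


class TestTermFeatures:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("P_TAL", {"P_TAL"}),
            ("P_TAL^2", {"P_TAL"}),
            ("P_TAL:CDS_TAL", {"P_TAL", "CDS_TAL"}),
            ("P_4CL:P_CHI", {"P_4CL", "P_CHI"}),
        ],
    )
    def test_feature_extraction(self, term, expected):
        assert term_features(term) == expected


class TestBackwardElimination:
    def test_recovers_single_true_term(self, library, scale):
        records = make_records(library, 40, seed=1)
        design = build_design_matrix(records, scale, library)
        rng = np.random.default_rng(0)
        y = 2.0 * design["P_TAL"] + 5.0 + 0.01 * rng.standard_normal(len(design))
        fit, trace = backward_eliminate(design, y, r2_floor=0.9, p_ceiling=0.15)
        assert "P_TAL" in fit.terms
        assert fit.params["P_TAL"] == pytest.approx(2.0, abs=0.05)
        # most spurious terms are gone and any survivors are negligible
        # (the p-ceiling stop can retain a few small-p-by-chance terms)
        assert len(fit.terms) < design.shape[1] / 2
        junk = [t for t in fit.terms if t != "P_TAL"]
        assert all(abs(fit.params[t]) < 0.1 for t in junk)

    def test_already_final_model_untouched(self):
        X = random_design(40, 2, 6)
        rng = np.random.default_rng(7)
        y = 3 * X["x0"] - 2 * X["x1"] + 0.05 * rng.standard_normal(40)
        fit, trace = backward_eliminate(X, y)
        assert fit.terms == ["x0", "x1"] and trace.steps == []

    def test_marginality_protects_linear_under_quadratic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        X = pd.DataFrame({"P_TAL": x, "P_TAL^2": x**2})
        y = 4 * x**2 + 0.01 * rng.standard_normal(50)  # linear term is junk
        fit, trace = backward_eliminate(X, y, r2_floor=0.0, p_ceiling=0.15)
        # the quadratic term must be dropped before its main effect ever can
        if "P_TAL" not in fit.terms:
            removed = trace.removed_terms()
            assert removed.index("P_TAL^2") < removed.index("P_TAL")

    def test_r2_non_increasing_along_trace(self, modelling_data):
        _filtered, design, titer = modelling_data
        fit, trace = backward_eliminate(design, titer, r2_floor=0.0, p_ceiling=0.15)
        r2s = [fit_ols(design, titer).r2] + [s["r2_after"] for s in trace.steps]
        assert all(b <= a + 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_initial_model_below_floor_warns(self):
        X = random_design(30, 3, 9)
        y = np.random.default_rng(10).normal(size=30)  # pure noise, R2 tiny
        with pytest.warns(UserWarning, match="floor"):
            fit, trace = backward_eliminate(X, y, r2_floor=0.9)
        assert trace.steps == [] and fit.terms == list(X.columns)


class TestLooPredict:
    def test_two_point_intercept_only(self):
        design = pd.DataFrame(index=[0, 1])
        preds, r2 = loo_predict([], design, np.array([1.0, 3.0]))
        np.testing.assert_allclose(preds, [3.0, 1.0])

    def test_matches_hat_matrix_identity(self):
        # held-out residual y_i - yhat_(-i) equals e_i / (1 - h_ii)
        X = random_design(15, 4, 11)
        rng = np.random.default_rng(12)
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.normal(size=15)
        y = np.asarray(y)
        preds, _ = loo_predict(list(X.columns), X, y)
        Xa = np.column_stack([np.ones(15), X.to_numpy()])
        H = Xa @ np.linalg.solve(Xa.T @ Xa, Xa.T)
        e = y - H @ y
        expected = y - e / (1 - np.diag(H))
        np.testing.assert_allclose(preds, expected, atol=1e-8)

    def test_noiseless_linear_loo_r2_is_one(self):
        X = random_design(20, 2, 13)
        y = 2 * X["x0"] - X["x1"] + 1.0
        _preds, r2 = loo_predict(list(X.columns), X, y)
        assert r2 == pytest.approx(1.0, abs=1e-10)


class TestPredictAndRank:
    def test_constant_model_ranks_in_enumeration_order(self, scale):
        lib = make_library(n_promoters=2)
        records = make_records(lib, 25, seed=14)
        design = build_design_matrix(records, scale, lib)
        cds_levels = design.attrs["cds_levels"]
        y = np.full(len(design), 7.0)
        fit = fit_ols(design[[]], y)  # intercept-only: constant prediction
        space = enumerate_space(lib)
        ranking = predict_and_rank(fit, space, scale, lib, cds_levels, k=5)
        np.testing.assert_allclose(ranking["predicted_titer_mg_L"], 7.0)
        # ties broken by enumeration order: row i is space[i]
        for i in range(5):
            g = space[i].as_dict()
            assert ranking.iloc[i]["P_TAL"] == g["TAL"][0]
            assert ranking.iloc[i]["CDS_CHI"] == g["CHI"][1]

    def test_monotone_single_term_argmax_at_extreme_promoter(self, scale):
        lib = make_library(n_promoters=3)
        records = make_records(lib, 25, seed=16)
        design = build_design_matrix(records, scale, lib)
        cds_levels = design.attrs["cds_levels"]
        rng = np.random.default_rng(17)
        y = 3.0 * design["P_TAL"] + 0.001 * rng.standard_normal(len(design))
        fit = fit_ols(design[["P_TAL"]], y)
        space = enumerate_space(lib)
        ranking = predict_and_rank(fit, space, scale, lib, cds_levels)
        # strongest TAL promoter must fill the top of the table
        strongest = max(lib.operon("TAL").promoters, key=lambda p: p.tif).id
        assert set(ranking.head(10)["P_TAL"]) == {strongest}

    def test_negative_predictions_survive_unless_clipped(self, scale):
        lib = make_library(n_promoters=3)
        records = make_records(lib, 25, seed=18)
        design = build_design_matrix(records, scale, lib)
        cds_levels = design.attrs["cds_levels"]
        y = -10.0 + 0.0 * design["P_TAL"]
        fit = fit_ols(design[["P_TAL"]], y + np.random.default_rng(19).normal(0, 0.01, len(design)))
        space = enumerate_space(lib)
        raw = predict_and_rank(fit, space, scale, lib, cds_levels)
        clipped = predict_and_rank(fit, space, scale, lib, cds_levels, clip_negative=True)
        assert raw["predicted_titer_mg_L"].min() < 0
        assert clipped["predicted_titer_mg_L"].min() == 0.0
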