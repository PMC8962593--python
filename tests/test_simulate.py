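import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathwayopt.defaults import default_hill, default_landscape
from pathwayopt.preprocess import scale_from_library
from pathwayopt.simulate import (
    HillParams,
    SyntheticLandscape,
    fit_hill,
    hill_response,
    normalize_fluorescence,
    select_range_covering_subset,
    simulate_screen,
    simulate_titer,
)
from pathwayopt.space import sample_assembly


class TestHillResponse:
    def test_basal_at_zero_and_half_saturation_at_K(self):
        p = HillParams(a=100.0, M=1000.0, n=1.5, K=20.0)
        assert hill_response(0.0, p) == pytest.approx(p.a)
        assert hill_response(p.K, p) == pytest.approx(p.a + (p.M - p.a) / 2)

    def test_saturates_to_maximum(self):
        p = HillParams(a=100.0, M=1000.0, n=1.0, K=20.0)
        assert hill_response(1e6 * p.K, p) == pytest.approx(p.M, abs=1e-4 * p.M)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_response(-1.0, HillParams(a=0.0, M=1.0, n=1.0, K=1.0))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        a=st.floats(0.0, 500.0),
        span=st.floats(1.0, 5000.0),
        n=st.floats(0.2, 5.0),
        K=st.floats(0.01, 500.0),
    )
    def test_bounded_and_monotone(self, a, span, n, K):
        p = HillParams(a=a, M=a + span, n=n, K=K)
        c = np.linspace(0, 10 * K, 200)
        f = hill_response(c, p)
        assert np.all(f >= p.a - 1e-9) and np.all(f <= p.M + 1e-9)
        assert np.all(np.diff(f) > -1e-12)


class TestFitHill:
    def test_noiseless_parameters_recovered(self):
        truth = HillParams(a=100.0, M=1000.0, n=1.5, K=20.0)
        c = np.concatenate([[0.0], np.geomspace(0.5, 100.0, 14)])
        fit, diag = fit_hill(c, hill_response(c, truth))
        for name in ("a", "M", "n", "K"):
            assert getattr(fit, name) == pytest.approx(
                getattr(truth, name), rel=1e-4
            ), name
        assert diag["rss"] < 1e-8

    def test_flat_curve_rejected(self):
        c = np.array([0.0, 1.0, 10.0, 100.0])
        with pytest.raises(ValueError, match="dynamic range"):
            fit_hill(c, np.full_like(c, 500.0))

    def test_K_recovered_under_noise_monte_carlo(self):
        truth = HillParams(a=100.0, M=1000.0, n=1.5, K=20.0)
        c = np.concatenate([[0.0], np.geomspace(0.5, 100.0, 11)])
        clean = hill_response(c, truth)
        errs = []
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            noisy = clean * (1 + 0.05 * rng.standard_normal(len(c)))
            fit, _ = fit_hill(c, noisy, n_restarts=10, seed=seed)
            errs.append(abs(fit.K - truth.K) / truth.K)
        errs = np.array(errs)
        # K is the softest Hill parameter: the typical (median) estimate is
        # within 15% of truth; gross failures are absent
        assert np.median(errs) < 0.15
        assert np.quantile(errs, 0.9) < 0.35


class TestNormalizeFluorescence:
    def test_direct_arithmetic(self):
        assert normalize_fluorescence(350, 50, 0.7, 0.2) == pytest.approx(600.0)

    def test_blank_fluorescence_gives_zero(self):
        assert normalize_fluorescence(50, 50, 0.7, 0.2) == 0.0

    def test_no_growth_is_an_error(self):
        with pytest.raises(ValueError, match="growth"):
            normalize_fluorescence(350, 50, 0.2, 0.2)


class TestSimulateTiter:
    def test_constant_landscape(self, library, scale):
        lan = SyntheticLandscape(baseline=5.0, noise_cv=0.0)
        for cfg in sample_assembly(library, 5, seed=0):
            assert simulate_titer(cfg, lan, library, scale, seed=0) == 5.0

    def test_single_linear_coefficient_closed_form(self, library, scale):
        lan = SyntheticLandscape(
            baseline=10.0, linear_coefs={"TAL": 3.0}, noise_cv=0.0
        )
        lo = sample_assembly(library, 1, seed=0)[0]
        # force TAL promoter to the endpoints of the linlog scale
        weakest = lo.as_dict() | {"TAL": ("P_B1", lo.cds_id("TAL"))}
        strongest = lo.as_dict() | {"TAL": ("P_B10", lo.cds_id("TAL"))}
        from pathwayopt.space import PathwayConfig

        t_lo = simulate_titer(PathwayConfig.from_dict(weakest), lan, library, scale, 0)
        t_hi = simulate_titer(PathwayConfig.from_dict(strongest), lan, library, scale, 0)
        assert t_hi - t_lo == pytest.approx(6.0, abs=1e-12)

    def test_default_screen_titer_envelope(self, screen):
        # 190-colony default screen spans the order of magnitude of a real
        # screen: a couple of mg/L up to the mid-twenties
        titers = np.array([c.true_titer for c in screen])
        assert 10.0 < titers.max() < 45.0
        assert titers.min() < 5.0
        assert np.ptp(titers) > 10.0


class TestSimulateScreen:
    def test_colony_count_and_finiteness(self, screen):
        assert len(screen) == 190
        for c in screen:
            assert np.isfinite([c.true_titer, c.fl, c.od, c.fl_over_od]).all()

    def test_same_seed_identical(self, library):
        lan, hill = default_landscape(), default_hill()
        a = simulate_screen(library, lan, hill, 25, seed=4)
        b = simulate_screen(library, lan, hill, 25, seed=4)
        assert [(c.config, c.fl, c.od) for c in a] == [
            (c.config, c.fl, c.od) for c in b
        ]

    def test_noiseless_readout_preserves_titer_ranking(self, library):
        from dataclasses import replace

        lan = replace(default_landscape(), noise_cv=0.0)
        screen = simulate_screen(
            library, lan, default_hill(), 60, seed=2,
            readout_cv=0.0, od_sd=0.0,
        )
        titers = np.array([c.true_titer for c in screen])
        ratios = np.array([c.fl_over_od for c in screen])
        # titer ordered by fluorescence must be non-decreasing (Hill is
        # strictly increasing, so ranking carries over exactly up to ties)
        assert np.all(np.diff(titers[np.argsort(ratios)]) >= -1e-9)
        assert np.all(np.diff(ratios[np.argsort(titers)]) >= -1e-9)


class TestRangeCoveringSelection:
    def test_count_and_extremes_included(self, screen):
        sel = select_range_covering_subset(screen, 35)
        assert len(sel) == 35
        ratios = [c.fl_over_od for c in screen]
        sel_ratios = [c.fl_over_od for c in sel]
        assert max(ratios) in sel_ratios and min(ratios) in sel_ratios

    def test_select_all_is_identity_as_a_set(self, screen):
        sel = select_range_covering_subset(screen, len(screen))
        assert set(id(c) for c in sel) == set(id(c) for c in screen)

    def test_two_picks_are_the_extremes(self, screen):
        sel = select_range_covering_subset(screen, 2)
        ratios = [c.fl_over_od for c in screen]
        assert sorted(c.fl_over_od for c in sel) == sorted([max(ratios), min(ratios)])

    @pytest.mark.parametrize("method", ["value", "rank"])
    def test_selected_spread_covers_the_screen(self, screen, method):
        sel = select_range_covering_subset(screen, 35, method=method)
        spread = np.ptp([c.fl_over_od for c in sel])
        full = np.ptp([c.fl_over_od for c in screen])
        assert spread >= 0.95 * full

    def test_weak_variants_underrepresented_in_value_selection(self, screen):
        sel = select_range_covering_subset(screen, 35, method="value")
        n_weak = sum(
            1 for c in sel
            if c.config.cds_id("4CL") == "At4CL" or c.config.cds_id("CHS") == "PhCHS"
        )
        pool = sum(
            1 for c in screen
            if c.config.cds_id("4CL") == "At4CL" or c.config.cds_id("CHS") == "PhCHS"
        ) / len(screen)
        assert n_weak / 35 < pool  # depleted relative to the screened pool
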