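"""Monte Carlo sampling structure, determinism and interval behaviour."""

import numpy as np
import pandas as pd
import pytest

from pmslt import (MonteCarloResult, ScenarioConfig, UncertaintySpec,
                   run_monte_carlo, sample_draw)
from pmslt.inputs import AGE_BANDS, DISEASES
from pmslt.synthetic import constant_risk_functions, single_cohort_table


@pytest.fixture()
def small_setup():
    cfg = ScenarioConfig(horizons=("lifetime",), discount_rates=(0.0,))
    return single_cohort_table(), constant_risk_functions(1.6), cfg


class TestSampleDraw:
    def test_degenerate_spec_reproduces_central_values(self, table2, risks, cfg):
        draw = sample_draw(table2, risks, cfg, UncertaintySpec().zeroed(),
                           np.random.default_rng(0))
        assert draw.table.strata == table2.strata
        assert draw.risks.rr == risks.rr
        assert draw.config.sbp_effect_mmhg == cfg.sbp_effect_mmhg
        assert draw.config.exposure_time_fraction == cfg.central_time_fraction
        assert draw.redraws == 0

    def test_between_sex_correlation_is_one(self, table2, risks, cfg):
        draw = sample_draw(table2, risks, cfg, UncertaintySpec(),
                           np.random.default_rng(42))
        for band in AGE_BANDS:
            m = draw.table.stratum("male", band)
            f = draw.table.stratum("female", band)
            assert m.exposure_prev == f.exposure_prev
            for d in DISEASES:
                m0 = table2.stratum("male", band).diseases[d]
                f0 = table2.stratum("female", band).diseases[d]
                if m0.incidence > 0 and f0.incidence > 0:
                    assert (m.diseases[d].incidence / m0.incidence
                            == pytest.approx(f.diseases[d].incidence / f0.incidence,
                                             rel=1e-12))

    def test_prevalence_draws_stay_in_unit_interval(self, table2, risks, cfg):
        rng = np.random.default_rng(7)
        spec = UncertaintySpec()
        for _ in range(50):
            draw = sample_draw(table2, risks, cfg, spec, rng)
            for s in draw.table.strata:
                assert 0.0 <= s.exposure_prev <= 1.0

    def test_exposure_time_quantiles_match_printed_beta(self, table2, risks, cfg):
        rng = np.random.default_rng(11)
        spec = UncertaintySpec()
        draws = np.array([
            sample_draw(table2, risks, cfg, spec, rng).config.exposure_time_fraction
            for _ in range(2000)])
        assert np.median(draws) == pytest.approx(0.319, abs=0.02)
        assert np.percentile(draws, 2.5) == pytest.approx(0.176, abs=0.02)
        assert np.percentile(draws, 97.5) == pytest.approx(0.490, abs=0.03)

    def test_spread_shrinks_with_sd(self, table2, risks, cfg):
        def spread(spec, seed=5, n=300):
            rng = np.random.default_rng(seed)
            vals = [sample_draw(table2, risks, cfg, spec, rng)
                    .table.stratum("male", "60-64").diseases["ihd"].incidence
                    for _ in range(n)]
            return float(np.ptp(vals))

        full = spread(UncertaintySpec())
        half = spread(UncertaintySpec(incidence_log_sd=0.025))
        zero = spread(UncertaintySpec().zeroed())
        assert full > half > zero == 0.0


class TestRunMonteCarlo:
    def test_seed_determinism_is_bitwise(self, small_setup):
        table, risks, cfg = small_setup
        a = run_monte_carlo(table, risks, cfg, iterations=3, seed=7)
        b = run_monte_carlo(table, risks, cfg, iterations=3, seed=7)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert a.lo == b.lo and a.hi == b.hi

    def test_degenerate_spec_collapses_interval(self, small_setup):
        table, risks, cfg = small_setup
        res = run_monte_carlo(table, risks, cfg, UncertaintySpec().zeroed(),
                              iterations=4, seed=1)
        cell = ("lifetime", 0.0)
        assert res.lo[cell] == pytest.approx(res.central[cell], rel=1e-12)
        assert res.hi[cell] == pytest.approx(res.central[cell], rel=1e-12)

    def test_point_mass_percentiles(self):
        draws = pd.DataFrame({"('lifetime', 0.0)": [2.0] * 10})
        res = MonteCarloResult(cells=(("lifetime", 0.0),),
                               central={("lifetime", 0.0): 2.0},
                               draws=draws, iterations=10, seed=0, redraws=0)
        assert res.lo[("lifetime", 0.0)] == res.hi[("lifetime", 0.0)] == 2.0

    def test_too_few_iterations_rejected(self, small_setup):
        table, risks, cfg = small_setup
        with pytest.raises(ValueError):
            run_monte_carlo(table, risks, cfg, iterations=1, seed=0)

    def test_summary_frame_has_all_cells(self, small_setup):
        table, risks, cfg = small_setup
        res = run_monte_carlo(table, risks, cfg, iterations=3, seed=2)
        frame = res.to_frame()
        assert set(frame.columns) >= {"horizon", "discount_rate", "central",
                                      "mean", "ui_lo", "ui_hi"}
        assert len(frame) == len(cfg.horizons) * len(cfg.discount_rates)
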