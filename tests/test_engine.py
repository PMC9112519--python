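"""Scenario orchestration: arms, aggregation, league table."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from pmslt import (PMSLT, ScenarioConfig, horizon_aggregate,
                   league_table_report, per_target_population, run_scenario)
from pmslt.inputs import EpiTable
from pmslt.synthetic import constant_risk_functions, single_cohort_table


@pytest.fixture(scope="module")
def hand_setup():
    """Single cohort with round numbers: m=0.01, i=0.02, f=0.1, pi=0.5,
    e^{beta delta}=2, dr=0.1, yld=0.1."""
    cfg = ScenarioConfig(t_cold=10.0, t_target=20.0, sbp_effect_mmhg=10.0,
                         rct_contrast_c=10.0, exposure_time_fraction=0.5)
    table = single_cohort_table(age_group="60-64", n=1000.0, acmr=0.01,
                                incidence=0.02, case_fatality=0.1,
                                disability=0.1, yld_prop=0.1, exposure_prev=0.5)
    risks = constant_risk_functions(4.0)  # beta*delta = ln(4)/10 * 5 = ln 2
    return table, risks, cfg


def hand_oracle(n_cycles=3, m=0.01, i=0.02, f=0.1, dr=0.1, yld=0.1, n=1000.0):
    """Straight-line spreadsheet-style recomputation of both arms."""
    pif = 0.5 * (2 - 1) / (0.5 * 2 + 0.5)  # = 1/3

    def disease(i_eff):
        p0 = i / (i + f)
        S, C = 1.0 - p0, p0
        prev, mort, ylds = [], [], []
        for _ in range(n_cycles):
            alive = S + C
            prev.append(C / alive)
            mort.append(f * C / alive)
            ylds.append(dr * C / alive)
            S1 = S * math.exp(-i_eff)
            C1 = C * math.exp(-f) + i_eff * S * (
                math.exp(-i_eff) - math.exp(-f)) / (f - i_eff)
            S, C = S1, C1
        return prev, mort, ylds

    _, mort_b, yld_b = disease(i)
    _, mort_s, yld_s = disease(i * (1 - pif))

    def arm(dm, dy):
        l, halys = 1.0, []
        for y in range(n_cycles):
            l1 = l * math.exp(-(m + dm[y]))
            L = (l + l1) / 2
            halys.append(L * (1 - (yld + dy[y])) * n)
            l = l1
        return halys

    bau = arm([0.0] * n_cycles, [0.0] * n_cycles)
    scn = arm([ms - mb for ms, mb in zip(mort_s, mort_b)],
              [ys - yb for ys, yb in zip(yld_s, yld_b)])
    return sum(bau), sum(scn)


class TestRunScenario:
    def test_three_cycle_totals_match_hand_recomputation(self, hand_setup):
        table, risks, cfg = hand_setup
        res = PMSLT(table, risks, cfg).fit()
        bau3 = horizon_aggregate(res.bau, 3, 0.0)["total"]
        scn3 = horizon_aggregate(res.scenario, 3, 0.0)["total"]
        oracle_bau, oracle_scn = hand_oracle()
        assert bau3 == pytest.approx(oracle_bau, abs=1e-9)
        assert scn3 == pytest.approx(oracle_scn, abs=1e-9)

    def test_zero_temperature_lift_gains_exactly_zero(self, table2, risks):
        cfg = ScenarioConfig(t_cold=20.0, t_target=20.0)
        res = PMSLT(table2, risks, cfg).fit()
        assert res.haly_gain("lifetime", 0.0) == 0.0
        assert res.haly_gain(10, 0.03) == 0.0

    def test_bau_invariant_to_risks_and_temperature(self, table2, risks, cfg):
        a = run_scenario(table2, None, cfg, "bau")
        b = run_scenario(table2, risks, cfg.with_(t_target=30.0), "bau")
        pd.testing.assert_frame_equal(a.lifetable, b.lifetable)

    def test_intervention_requires_risks(self, table2, cfg):
        with pytest.raises(ValueError, match="requires risk"):
            run_scenario(table2, None, cfg, "intervention")
        with pytest.raises(ValueError, match="unknown mode"):
            run_scenario(table2, None, cfg, "magic")

    def test_doubling_population_doubles_totals_not_per_1000(self, table2, risks, cfg):
        doubled = EpiTable([dataclasses.replace(s, n=2 * s.n)
                            for s in table2.strata])
        r1 = PMSLT(table2, risks, cfg).fit()
        r2 = PMSLT(doubled, risks, cfg).fit()
        assert r2.haly_gain() == pytest.approx(2 * r1.haly_gain(), rel=1e-12)
        assert r2.per_1000_gain() == pytest.approx(r1.per_1000_gain(), rel=1e-12)

    def test_gains_additive_over_cohorts(self, table2, risks, cfg):
        res = PMSLT(table2, risks, cfg).fit()
        per_cohort = res.lifetable.groupby(["sex", "age_group"])["haly_gain"].sum()
        assert per_cohort.sum() == pytest.approx(res.haly_gain(), rel=1e-12)
        assert (per_cohort >= -1e-9).all()


class TestHorizonAggregate:
    def test_lifetime_is_plain_sum(self, hand_setup):
        table, risks, cfg = hand_setup
        res = run_scenario(table, risks, cfg, "bau")
        agg = horizon_aggregate(res, "lifetime", 0.0)
        assert agg["total"] == pytest.approx(res.lifetable.halys.sum(), rel=1e-12)
        assert agg["per_1000"] == pytest.approx(agg["total"] / (res.total_n / 1000))

    def test_window_is_half_open(self, hand_setup):
        table, risks, cfg = hand_setup
        res = run_scenario(table, risks, cfg, "bau")
        df = res.lifetable
        ten = horizon_aggregate(res, 10, 0.0)["total"]
        manual = df.loc[df.year.between(2016, 2025), "halys"].sum()
        with_year_ten = df.loc[df.year.between(2016, 2026), "halys"].sum()
        assert ten == pytest.approx(manual, rel=1e-12)
        assert ten < with_year_ten  # year index 10 is excluded

    def test_discounting_reduces_totals(self, hand_setup):
        table, risks, cfg = hand_setup
        res = run_scenario(table, risks, cfg, "bau")
        assert (horizon_aggregate(res, "lifetime", 0.03)["total"]
                < horizon_aggregate(res, "lifetime", 0.0)["total"])

    def test_unknown_horizon_rejected(self, hand_setup):
        table, risks, cfg = hand_setup
        res = run_scenario(table, risks, cfg, "bau")
        with pytest.raises(ValueError, match="unknown horizon"):
            horizon_aggregate(res, "forever", 0.0)


class TestLeagueTable:
    COMPARATORS = pd.DataFrame({
        "intervention": ["dietary advice", "lifestyle program", "heart health program"],
        "halys_per_1000": [0.017, 0.024, 0.141],
        "ui_lo": [0.01, 0.01, 0.071],
        "ui_hi": [0.027, 0.027, 0.221],
    })

    def test_empty_comparators_single_row(self):
        df = league_table_report(0.447, 0.064, 1.34, None)
        assert len(df) == 1 and df.loc[0, "rank"] == 1

    def test_model_outranks_recommended_interventions(self):
        df = league_table_report(0.447, 0.064, 1.34, self.COMPARATORS)
        assert df.loc[0, "intervention"] == "Eradication of cold housing"
        assert list(df["halys_per_1000"]) == sorted(df["halys_per_1000"], reverse=True)

    def test_ties_broken_by_name(self):
        tied = pd.DataFrame({"intervention": ["zeta", "alpha"],
                             "halys_per_1000": [0.5, 0.5],
                             "ui_lo": [None, None], "ui_hi": [None, None]})
        df = league_table_report(0.5, None, None, tied)
        assert list(df["intervention"]) == [
            "Eradication of cold housing", "alpha", "zeta"]

    def test_malformed_comparators_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            league_table_report(0.5, None, None,
                                pd.DataFrame({"name": ["x"], "value": [1.0]}))


class TestTargetPopulationScaling:
    def test_per_exposed_rescaling(self):
        assert per_target_population(1.64, 0.0574) == pytest.approx(28.57, abs=0.01)
        with pytest.raises(ValueError):
            per_target_population(1.0, 0.0)
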