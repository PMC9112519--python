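"""Input-table loading, validation, unit conversion and coherence checks."""

import math

import pandas as pd
import pytest

from pmslt import (check_epi_coherence, load_cohort_inputs,
                   load_risk_functions, write_cohort_inputs)
from pmslt.inputs import (AGE_BANDS, ValidationError, band_for_age,
                          cycle_band_weights, _data_path)


def _fixture_frame():
    return pd.read_csv(_data_path("table2_2016.csv"), comment="#")


class TestLoadCohortInputs:
    def test_full_fixture_load(self, table2):
        assert len(table2.strata) == 42
        assert table2.total_n == 15_560_018

    def test_known_stratum_values(self, table2):
        s = table2.stratum("male", "45-49")
        assert s.n == 499_837
        assert s.exposure_prev == pytest.approx(0.0749, abs=1e-12)
        assert s.acmr == pytest.approx(237e-5, rel=1e-12)
        assert s.diseases["ihd"].incidence == pytest.approx(177e-5, rel=1e-12)
        assert s.diseases["ihd"].case_fatality == 0.024
        assert s.yld_prop == 0.134

    def test_unit_conversion_is_exact(self, table2):
        raw = _fixture_frame().set_index(["sex", "age_group"])
        for sex in ("male", "female"):
            for band in AGE_BANDS:
                s = table2.stratum(sex, band)
                assert s.acmr == float(raw.loc[(sex, band), "mortality_per_100k"]) * 1e-5

    def test_sbp_absent_below_15(self, table2):
        assert not table2.stratum("female", "10-14").has_sbp
        assert table2.stratum("female", "15-19").sbp_mean == 107.6

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        _fixture_frame().head(0).to_csv(p, index=False)
        with pytest.raises(ValidationError, match="no strata"):
            load_cohort_inputs(p)

    @pytest.mark.parametrize("mutate, match", [
        (lambda df: df.drop(index=0), "missing stratum"),
        (lambda df: pd.concat([df, df.head(1)]), "duplicate stratum"),
        (lambda df: df.assign(mortality_per_100k=df.mortality_per_100k.where(
            df.index != 3, -1)), "negative rate"),
        (lambda df: df.assign(cold_prevalence_pct=df.cold_prevalence_pct.where(
            df.index != 3, 120.0)), "prevalence outside"),
        (lambda df: df.drop(columns=["yld_prop"]), "missing columns"),
    ])
    def test_validation_errors_name_the_problem(self, tmp_path, mutate, match):
        p = tmp_path / "bad.csv"
        mutate(_fixture_frame()).to_csv(p, index=False)
        with pytest.raises(ValidationError, match=match):
            load_cohort_inputs(p)

    def test_round_trip_is_identity(self, table2, tmp_path):
        p = tmp_path / "rt.csv"
        write_cohort_inputs(table2, p)
        again = load_cohort_inputs(p)
        assert again.strata == table2.strata


class TestRiskFunctions:
    def test_log_linear_slope(self, risks):
        assert risks.rr_per_10mmhg("ihd", "55-59") == 1.60
        assert risks.beta("ihd", "55-59") == pytest.approx(math.log(1.60) / 10)

    def test_uncovered_young_bands_have_zero_slope(self, risks):
        assert risks.beta("ihd", "0-4") == 0.0
        assert risks.beta("ihd", "20-24") == 0.0

    def test_inherit_younger_flag(self, tmp_path):
        r = load_risk_functions(
            _data_path("risk_functions_sbp_synthetic.csv"), inherit_younger=True)
        assert r.beta("ihd", "0-4") == r.beta("ihd", "25-29")

    @pytest.mark.parametrize("mutate, match", [
        (lambda df: pd.concat([df, df.head(1)]), "duplicate"),
        (lambda df: df.assign(rr_per_10mmhg=df.rr_per_10mmhg.where(
            df.index != 0, -2.0)), "must be > 0"),
        (lambda df: df[df.disease != "ihd"], "missing disease"),
        (lambda df: df[df.age_group != "55-59"], "gaps"),
    ])
    def test_risk_validation(self, tmp_path, mutate, match):
        df = pd.read_csv(_data_path("risk_functions_sbp_synthetic.csv"), comment="#")
        p = tmp_path / "rr.csv"
        mutate(df).to_csv(p, index=False)
        with pytest.raises(ValidationError, match=match):
            load_risk_functions(p)


class TestCoherence:
    def test_zero_incidence_not_flagged(self, table2):
        # young strata have i == 0 with f > 0: implied prevalence 0, no flag
        rep = check_epi_coherence(table2)
        flagged = {(f.sex, f.age_group) for f in rep.flags}
        assert ("male", "0-4") not in flagged

    def test_impossible_mortality_flagged(self, table2):
        rep = check_epi_coherence(table2)
        kinds = {f.kind for f in rep.flags}
        assert kinds <= {"excess_mortality", "disability_weight"}
        # frozen regression: middle-aged male strata where steady-state CVD
        # mortality slightly exceeds the all-cause rate
        flagged = sorted((f.sex, f.age_group) for f in rep.flags)
        assert flagged == [("male", "45-49"), ("male", "50-54"), ("male", "55-59")]

    def test_report_is_relaxed_by_factor(self, table2):
        assert check_epi_coherence(table2, mortality_factor=1.5).ok


class TestBandLookup:
    def test_band_for_age_half_open(self):
        assert band_for_age(49.999) == "45-49"
        assert band_for_age(50.0) == "50-54"
        assert band_for_age(108.0) == "100-104"

    def test_cycle_weights_blend_at_boundaries(self):
        assert cycle_band_weights(47.5, 0) == [("45-49", 1.0)]
        parts = cycle_band_weights(47.5, 2)  # cycle [49.5, 50.5)
        assert parts[0][0] == "45-49" and parts[1][0] == "50-54"
        assert parts[0][1] == pytest.approx(0.5)
        assert sum(w for _, w in parts) == pytest.approx(1.0)
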