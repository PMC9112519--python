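"""Age/sex-stratified epidemiological input tables.

The model consumes one row per sex x 5-year age band: population count,
cold-housing exposure prevalence, all-cause mortality, all-cause morbidity
(the YLD proportion used to health-adjust life years), the systolic blood
pressure distribution, and per-disease incidence, case fatality and
disability rates for ischemic heart disease, ischemic stroke and
haemorrhagic stroke.

File convention: incidence, disability and mortality rates are stored per
100,000 persons (case fatality per person) and converted to per-person on
load; exposure prevalence is stored in percent.  Disability rates are YLD
per prevalent case, i.e. a disability weight.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DISEASES",
    "AGE_BANDS",
    "SBP_MIN_AGE",
    "CohortInputs",
    "DiseaseRates",
    "RiskFunctions",
    "EpiTable",
    "ValidationError",
    "load_cohort_inputs",
    "write_cohort_inputs",
    "load_risk_functions",
    "check_epi_coherence",
    "packaged_cohort_inputs",
    "packaged_risk_functions",
]

#: Modelled cardiovascular diseases (stroke subtypes run as parallel lifetables).
DISEASES = ("ihd", "isch_stroke", "hem_stroke")

#: The 21 five-year age bands of the base-year table.
AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(0, 105, 5))

#: Systolic blood pressure is not measured below this age; the SBP pathway
#: contributes no impact fraction there.
SBP_MIN_AGE = 15

SEXES = ("male", "female")

_RATE_SCALE = 1e-5  # per-100,000 file values -> per-person

_DISEASE_COLS = {
    "ihd": ("ihd_ir_per_100k", "ihd_cfr", "ihd_dr_per_100k"),
    "isch_stroke": (
        "isch_stroke_ir_per_100k",
        "isch_stroke_cfr",
        "isch_stroke_dr_per_100k",
    ),
    "hem_stroke": (
        "hem_stroke_ir_per_100k",
        "hem_stroke_cfr",
        "hem_stroke_dr_per_100k",
    ),
}

REQUIRED_COLUMNS = (
    "sex",
    "age_group",
    "n",
    "cold_prevalence_pct",
    "mortality_per_100k",
    "yld_prop",
    "sbp_mean",
    "sbp_sd",
) + tuple(c for cols in _DISEASE_COLS.values() for c in cols)


class ValidationError(ValueError):
    """Raised when an input table violates the schema or its invariants."""


def band_lower(age_group: str) -> int:
    return int(age_group.split("-")[0])


def band_midpoint(age_group: str) -> float:
    """Mid-band representative age (e.g. 45-49 -> 47.5)."""
    return band_lower(age_group) + 2.5


def band_for_age(age: float) -> str:
    """Age band containing ``age``, half-open [lower, lower+5); capped at the
    last band, whose rates are carried forward to age 110."""
    lo = min(int(age // 5) * 5, 100)
    return f"{lo}-{lo + 4}"


def cycle_band_weights(a0: float, y: int) -> list[tuple[str, float]]:
    """Bands overlapped by the annual cycle [a0+y, a0+y+1) with their
    time weights.

    Cohorts start at mid-band ages, so a cycle either sits inside one band or
    straddles a boundary; blending the two bands' rates by overlap keeps the
    discrete cumulative hazard aligned with the underlying band schedule
    (a whole-cycle assignment would shift every band window by half a year).
    """
    start = a0 + y
    b1 = band_for_age(start)
    b2 = band_for_age(start + 1.0 - 1e-9)
    if b1 == b2:
        return [(b1, 1.0)]
    w1 = band_lower(b2) - start
    return [(b1, w1), (b2, 1.0 - w1)]


@dataclass(frozen=True)
class DiseaseRates:
    """Per-disease base-year rates for one stratum (all per person-year,
    except ``disability`` which is YLD per prevalent case)."""

    incidence: float
    case_fatality: float
    disability: float

    def steady_state_prevalence(self) -> float:
        """Prevalence implied by constant incidence/case-fatality turnover."""
        if self.incidence + self.case_fatality <= 0.0:
            return 0.0
        return self.incidence / (self.incidence + self.case_fatality)


@dataclass(frozen=True)
class CohortInputs:
    """One sex x age-band stratum of the base-year input table."""

    sex: str
    age_group: str
    n: float
    exposure_prev: float
    acmr: float
    yld_prop: float
    sbp_mean: float | None
    sbp_sd: float | None
    diseases: Mapping[str, DiseaseRates]

    @property
    def has_sbp(self) -> bool:
        return self.sbp_mean is not None and self.sbp_sd is not None


class EpiTable:
    """Collection of the 42 strata with band lookups used by the engine."""

    def __init__(self, strata: Iterable[CohortInputs]):
        strata = list(strata)
        if not strata:
            raise ValidationError("no strata")
        self._by_key = {(s.sex, s.age_group): s for s in strata}
        if len(self._by_key) != len(strata):
            raise ValidationError("duplicate strata passed to EpiTable")
        self.strata: Sequence[CohortInputs] = tuple(strata)

    def stratum(self, sex: str, age_group: str) -> CohortInputs:
        return self._by_key[(sex, age_group)]

    def rates_at_age(self, sex: str, age: float) -> CohortInputs:
        """Stratum supplying rates for a cohort whose mid-cohort age is ``age``
        (last band carried forward beyond 104)."""
        return self.stratum(sex, band_for_age(age))

    def cycle_rates(self, sex: str, a0: float, y: int
                    ) -> tuple[float, float, dict[str, DiseaseRates]]:
        """Time-weighted (acmr, yld_prop, per-disease rates) for the annual
        cycle [a0+y, a0+y+1) of a cohort that started at mid-band age ``a0``."""
        parts = cycle_band_weights(a0, y)
        if len(parts) == 1:
            s = self.stratum(sex, parts[0][0])
            return s.acmr, s.yld_prop, dict(s.diseases)
        acmr = yld = 0.0
        dis = {d: [0.0, 0.0, 0.0] for d in DISEASES}
        for band, w in parts:
            s = self.stratum(sex, band)
            acmr += w * s.acmr
            yld += w * s.yld_prop
            for d in DISEASES:
                r = s.diseases[d]
                dis[d][0] += w * r.incidence
                dis[d][1] += w * r.case_fatality
                dis[d][2] += w * r.disability
        return acmr, yld, {d: DiseaseRates(*v) for d, v in dis.items()}

    @property
    def total_n(self) -> float:
        return float(sum(s.n for s in self.strata))

    @property
    def exposed_share(self) -> float:
        """Population-weighted cold-housing exposure prevalence."""
        return float(
            sum(s.n * s.exposure_prev for s in self.strata) / self.total_n
        )

    def replace_strata(self, strata: Iterable[CohortInputs]) -> "EpiTable":
        return EpiTable(strata)

    def to_frame(self) -> pd.DataFrame:
        # per-100k values rounded to 9 dp so that integer-valued fixture
        # rates survive the per-person <-> per-100k conversion bit-exactly
        back = lambda x: round(x / _RATE_SCALE, 9)
        rows = []
        for s in self.strata:
            row = {
                "sex": s.sex,
                "age_group": s.age_group,
                "n": s.n,
                "cold_prevalence_pct": round(s.exposure_prev * 100.0, 9),
                "mortality_per_100k": back(s.acmr),
                "yld_prop": s.yld_prop,
                "sbp_mean": np.nan if s.sbp_mean is None else s.sbp_mean,
                "sbp_sd": np.nan if s.sbp_sd is None else s.sbp_sd,
            }
            for d, (c_ir, c_cfr, c_dr) in _DISEASE_COLS.items():
                row[c_ir] = back(s.diseases[d].incidence)
                row[c_cfr] = s.diseases[d].case_fatality
                row[c_dr] = back(s.diseases[d].disability)
            rows.append(row)
        return pd.DataFrame(rows)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _row_to_stratum(row: pd.Series, idx) -> CohortInputs:
    sex, band = row["sex"], row["age_group"]
    where = f"row {idx} ({sex}, {band})"
    _check(sex in SEXES, f"{where}: unknown sex {sex!r} [column sex]")
    _check(band in AGE_BANDS, f"{where}: unknown age band {band!r} [column age_group]")
    n = float(row["n"])
    _check(n >= 0, f"{where}: negative population [column n]")
    prev = float(row["cold_prevalence_pct"]) / 100.0
    _check(0.0 <= prev <= 1.0, f"{where}: prevalence outside [0,1] [column cold_prevalence_pct]")
    acmr = float(row["mortality_per_100k"]) * _RATE_SCALE
    _check(acmr >= 0, f"{where}: negative rate [column mortality_per_100k]")
    yld = float(row["yld_prop"])
    _check(0.0 <= yld <= 1.0, f"{where}: yld_prop outside [0,1] [column yld_prop]")

    sbp_mean = row["sbp_mean"]
    sbp_sd = row["sbp_sd"]
    sbp_missing = pd.isna(sbp_mean) or pd.isna(sbp_sd)
    if band_lower(band) < SBP_MIN_AGE:
        _check(sbp_missing, f"{where}: SBP given below age {SBP_MIN_AGE} [column sbp_mean]")
        sbp_mean = sbp_sd = None
    else:
        _check(not sbp_missing, f"{where}: missing SBP [column sbp_mean]")
        sbp_mean, sbp_sd = float(sbp_mean), float(sbp_sd)
        _check(sbp_sd > 0, f"{where}: sbp_sd must be positive [column sbp_sd]")

    diseases = {}
    for d, (c_ir, c_cfr, c_dr) in _DISEASE_COLS.items():
        ir = float(row[c_ir]) * _RATE_SCALE
        cfr = float(row[c_cfr])
        dr = float(row[c_dr]) * _RATE_SCALE
        for val, col in ((ir, c_ir), (cfr, c_cfr), (dr, c_dr)):
            _check(val >= 0, f"{where}: negative rate [column {col}]")
        diseases[d] = DiseaseRates(ir, cfr, dr)
    return CohortInputs(sex, band, n, prev, acmr, yld, sbp_mean, sbp_sd, diseases)


def load_cohort_inputs(path, schema_version: str = "1") -> EpiTable:
    """Read and validate a base-year input table.

    Expects one row per sex x 5-year age band covering both sexes and all 21
    bands 0-4 .. 100-104.  Raises :class:`ValidationError` naming the offending
    row and column on any violation.
    """
    if schema_version != "1":
        raise ValidationError(f"unknown schema version {schema_version!r}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    _check(not missing, f"missing columns: {', '.join(missing)}")
    _check(len(df) > 0, "no strata")

    dup = df.duplicated(subset=["sex", "age_group"])
    if dup.any():
        i = int(dup.idxmax())
        raise ValidationError(
            f"row {i}: duplicate stratum ({df.loc[i, 'sex']}, {df.loc[i, 'age_group']})"
        )
    strata = [_row_to_stratum(row, idx) for idx, row in df.iterrows()]
    have = {(s.sex, s.age_group) for s in strata}
    for sex in SEXES:
        for band in AGE_BANDS:
            _check((sex, band) in have, f"missing stratum ({sex}, {band})")
    # preserve canonical ordering: male bands then female bands
    order = {(sex, band): i for i, (sex, band) in enumerate(
        (s, b) for s in SEXES for b in AGE_BANDS)}
    strata.sort(key=lambda s: order[(s.sex, s.age_group)])
    return EpiTable(strata)


def write_cohort_inputs(table: EpiTable, path) -> None:
    """Write a table back to CSV in the on-disk units (round-trips exactly
    up to float formatting)."""
    df = table.to_frame()
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class RiskFunctions:
    """Per-disease, per-age-band relative risks of disease incidence per
    10 mmHg systolic blood pressure, under a log-linear exposure-response:
    ``RR(x) = exp(beta * x)`` with ``beta = ln(rr_per_10mmhg) / 10``.
    """

    rr: Mapping[tuple[str, str], float]
    ci: Mapping[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    source: str = ""

    def rr_per_10mmhg(self, disease: str, age_group: str) -> float | None:
        return self.rr.get((disease, age_group))

    def beta(self, disease: str, age_group: str) -> float:
        """Log-RR per mmHg; 0 where no relative risk is defined (ages below
        the youngest covered band contribute no impact fraction)."""
        rr = self.rr.get((disease, age_group))
        return 0.0 if rr is None else float(np.log(rr)) / 10.0

    def beta_at_age(self, disease: str, age: float) -> float:
        return self.beta(disease, band_for_age(age))

    def beta_for_cycle(self, disease: str, a0: float, y: int) -> float:
        """Time-weighted log-RR slope over the cycle [a0+y, a0+y+1)."""
        return sum(w * self.beta(disease, band)
                   for band, w in cycle_band_weights(a0, y))

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted({d for d, _ in self.rr}))

    def scaled(self, multipliers: Mapping[str, float]) -> "RiskFunctions":
        """Return a copy with each disease's log-RRs multiplied (used by the
        uncertainty analysis)."""
        rr = {
            (d, b): float(np.exp(np.log(v) * multipliers.get(d, 1.0)))
            for (d, b), v in self.rr.items()
        }
        return RiskFunctions(rr=rr, ci=self.ci, source=self.source)


def load_risk_functions(path, inherit_younger: bool = False) -> RiskFunctions:
    """Read a (disease, age_group, rr_per_10mmhg[, rr_lo, rr_hi]) CSV.

    Each disease must cover a contiguous run of bands ending at 100-104;
    with ``inherit_younger`` bands below a disease's youngest entry inherit
    the nearest older band's value instead of contributing no risk.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("disease", "age_group", "rr_per_10mmhg"):
        _check(col in df.columns, f"missing column {col}")
    _check(len(df) > 0, "empty risk-function table")
    dup = df.duplicated(subset=["disease", "age_group"])
    _check(not dup.any(), "duplicate (disease, age_group) rows")
    missing = set(DISEASES) - set(df["disease"])
    _check(not missing, f"missing disease(s): {', '.join(sorted(missing))}")

    rr: dict[tuple[str, str], float] = {}
    ci: dict[tuple[str, str], tuple[float, float]] = {}
    for idx, row in df.iterrows():
        band = row["age_group"]
        _check(band in AGE_BANDS, f"row {idx}: unknown age band {band!r}")
        val = float(row["rr_per_10mmhg"])
        _check(val > 0, f"row {idx}: rr_per_10mmhg must be > 0")
        key = (row["disease"], band)
        rr[key] = val
        if "rr_lo" in df.columns and "rr_hi" in df.columns:
            lo, hi = float(row["rr_lo"]), float(row["rr_hi"])
            _check(0 < lo <= hi, f"row {idx}: invalid CI")
            ci[key] = (lo, hi)

    for d in sorted({d for d, _ in rr}):
        covered = [b for b in AGE_BANDS if (d, b) in rr]
        idxs = [AGE_BANDS.index(b) for b in covered]
        _check(
            idxs == list(range(min(idxs), max(idxs) + 1)),
            f"disease {d}: age-band coverage has gaps",
        )
        _check(
            covered[-1] == AGE_BANDS[-1],
            f"disease {d}: coverage must extend to {AGE_BANDS[-1]}",
        )
        if inherit_younger:
            youngest = covered[0]
            for b in AGE_BANDS[: AGE_BANDS.index(youngest)]:
                rr[(d, b)] = rr[(d, youngest)]
                if (d, youngest) in ci:
                    ci[(d, b)] = ci[(d, youngest)]
    return RiskFunctions(rr=rr, ci=ci, source=str(path))


@dataclass(frozen=True)
class CoherenceFlag:
    sex: str
    age_group: str
    disease: str
    kind: str
    detail: str


@dataclass(frozen=True)
class CoherenceReport:
    flags: tuple[CoherenceFlag, ...]

    @property
    def ok(self) -> bool:
        return not self.flags

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.flags],
                            columns=["sex", "age_group", "disease", "kind", "detail"])


def check_epi_coherence(table: EpiTable, mortality_factor: float = 1.0,
                        max_disability_weight: float = 1.0) -> CoherenceReport:
    """Internal consistency checks on a loaded table (report only, no mutation).

    Flags strata where the disease mortality implied by case fatality acting on
    the steady-state prevalence exceeds ``mortality_factor`` x the all-cause
    mortality rate (summed over diseases, a logical impossibility at factor 1),
    and disability weights above ``max_disability_weight``.
    """
    flags: list[CoherenceFlag] = []
    for s in table.strata:
        implied_mort = 0.0
        for d, rates in s.diseases.items():
            prev = rates.steady_state_prevalence()
            implied_mort += rates.case_fatality * prev
            if rates.disability > max_disability_weight:
                flags.append(CoherenceFlag(
                    s.sex, s.age_group, d, "disability_weight",
                    f"disability weight {rates.disability:.3f} > {max_disability_weight}"))
        if implied_mort > mortality_factor * s.acmr and implied_mort > 0:
            flags.append(CoherenceFlag(
                s.sex, s.age_group, "all", "excess_mortality",
                f"implied CVD mortality {implied_mort:.5f} exceeds "
                f"{mortality_factor:g} x all-cause rate {s.acmr:.5f}"))
    return CoherenceReport(tuple(flags))


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("pmslt").joinpath("data", name))


def packaged_cohort_inputs() -> EpiTable:
    """The packaged 2016 base-year table for the three Australian states."""
    return load_cohort_inputs(_data_path("table2_2016.csv"))


def packaged_risk_functions() -> RiskFunctions:
    """The packaged synthetic stand-in SBP relative-risk table (see the file
    header; substitute the published supplementary values when available)."""
    return load_risk_functions(_data_path("risk_functions_sbp_synthetic.csv"))
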