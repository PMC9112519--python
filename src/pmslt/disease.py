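"""Three-state disease lifetables.

Each cardiovascular disease runs per cohort as an independent
healthy (S) -> diseased (C) -> dead-from-disease (D) process with no
remission, in annual cycles.  Within a cycle the rates are constant and the
cycle is solved exactly (matrix-exponential solution of
dS/dt = -iS, dC/dt = iS - fC, dD/dt = fC), the standard proportional
multistate lifetable convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inputs import CohortInputs, EpiTable, band_midpoint

__all__ = ["DiseaseState", "TrendSpec", "DiseaseTrajectory",
           "step_disease", "run_disease_trajectory"]

#: |f - i| below which the f == i limiting form of the cycle solution is used.
_RATE_TOL = 1e-9


@dataclass(frozen=True)
class DiseaseState:
    """State of one disease lifetable at the start of a cycle.

    ``S``, ``C`` and ``D`` are proportions of the cohort's initial mass that
    are healthy, prevalent diseased and cumulatively dead from this disease.
    """

    S: float
    C: float
    D: float = 0.0

    @property
    def alive(self) -> float:
        return self.S + self.C

    @property
    def prevalence(self) -> float:
        """Prevalence among those alive in this (disease-only) lifetable."""
        return self.C / self.alive if self.alive > 0 else 0.0

    def mortality_rate(self, case_fatality: float) -> float:
        """Disease mortality rate per alive person this cycle."""
        return case_fatality * self.prevalence

    def yld_rate(self, disability: float) -> float:
        """Disease YLD per alive person: prevalence x per-case weight."""
        return self.prevalence * disability


@dataclass(frozen=True)
class TrendSpec:
    """Annual percentage changes (fractions/year, may be negative) applied
    multiplicatively to incidence and case fatality from the base year.
    Values default to 0 everywhere."""

    incidence_apc: dict = field(default_factory=dict)
    case_fatality_apc: dict = field(default_factory=dict)

    def incidence_factor(self, disease: str, years_elapsed: int) -> float:
        return (1.0 + self.incidence_apc.get(disease, 0.0)) ** years_elapsed

    def case_fatality_factor(self, disease: str, years_elapsed: int) -> float:
        return (1.0 + self.case_fatality_apc.get(disease, 0.0)) ** years_elapsed


def step_disease(state: DiseaseState, incidence: float,
                 case_fatality: float) -> DiseaseState:
    """Advance one annual cycle under constant rates.

    Exact solution:  S' = S e^{-i};
    C' = C e^{-f} + i S (e^{-i} - e^{-f}) / (f - i)   (f != i),
    with the limit C' = C e^{-f} + i S e^{-i} at f == i.  D absorbs the mass
    balance, so S + C + D is conserved exactly.
    """
    i, f = incidence, case_fatality
    if i < 0 or f < 0:
        raise ValueError("disease rates must be non-negative")
    S, C, D = state.S, state.C, state.D
    ei, ef = math.exp(-i), math.exp(-f)
    S1 = S * ei
    if abs(f - i) < _RATE_TOL:
        C1 = C * ef + i * S * ei
    else:
        C1 = C * ef + i * S * (ei - ef) / (f - i)
    D1 = D + (S - S1) + (C - C1)
    return DiseaseState(S1, C1, D1)


@dataclass(frozen=True)
class DiseaseTrajectory:
    """Per-year disease lifetable quantities for one cohort and disease.

    Arrays are indexed by simulation year; ``prevalence``, ``mortality`` and
    ``yld`` refer to the cycle starting that year (rates per alive person).
    """

    disease: str
    years: np.ndarray
    S: np.ndarray
    C: np.ndarray
    D: np.ndarray
    prevalence: np.ndarray
    mortality: np.ndarray
    yld: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years, "S": self.S, "C": self.C, "D": self.D,
            "prevalence": self.prevalence, "mortality": self.mortality,
            "yld": self.yld,
        })


def run_disease_trajectory(table: EpiTable, cohort: CohortInputs, disease: str,
                           pif_series: np.ndarray, trend: TrendSpec | None = None,
                           horizon: int | None = None,
                           initial_prevalence: float | None = None,
                           ) -> DiseaseTrajectory:
    """Run one disease lifetable for one cohort.

    The cohort starts at its mid-band age; each cycle uses the 5-year band
    rates blended by the cycle's overlap with the bands it spans (last band
    carried forward to age 110).  Incidence in year y is
    ``i_band * trend * (1 - pif_series[y])``; the impact fraction never
    touches case fatality.  The initial diseased proportion defaults to the
    steady state implied by the base-year rates, ``i / (i + f)``.

    ``horizon`` defaults to the number of cycles until the cohort reaches
    age 110.
    """
    trend = trend or TrendSpec()
    a0 = band_midpoint(cohort.age_group)
    n_years = math.ceil(110.0 - a0) if horizon is None else int(horizon)
    if n_years <= 0:
        raise ValueError("horizon must be positive")
    pif_series = np.asarray(pif_series, dtype=float)
    if pif_series.shape[0] < n_years:
        raise ValueError("pif_series shorter than horizon")

    base = cohort.diseases[disease]
    if initial_prevalence is None:
        initial_prevalence = base.steady_state_prevalence()
    state = DiseaseState(S=1.0 - initial_prevalence, C=initial_prevalence)

    S = np.empty(n_years + 1)
    C = np.empty(n_years + 1)
    D = np.empty(n_years + 1)
    prev = np.empty(n_years)
    mort = np.empty(n_years)
    yld = np.empty(n_years)
    S[0], C[0], D[0] = state.S, state.C, state.D

    for y in range(n_years):
        _, _, by_disease = table.cycle_rates(cohort.sex, a0, y)
        rates = by_disease[disease]
        i = rates.incidence * trend.incidence_factor(disease, y) * (1.0 - pif_series[y])
        f = rates.case_fatality * trend.case_fatality_factor(disease, y)
        if i < 0 or f < 0:
            raise ValueError("trend produced a negative rate")
        prev[y] = state.prevalence
        mort[y] = state.mortality_rate(f)
        yld[y] = state.yld_rate(rates.disability)
        state = step_disease(state, i, f)
        S[y + 1], C[y + 1], D[y + 1] = state.S, state.C, state.D

    return DiseaseTrajectory(
        disease=disease, years=np.arange(n_years + 1),
        S=S, C=C, D=D, prevalence=prev, mortality=mort, yld=yld,
    )
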