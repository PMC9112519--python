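"""Scenario runner: orchestrates the main and disease lifetables per cohort.

The 42 base-year strata are simulated as closed cohorts in annual cycles from
the base year until each reaches age 110.  Business as usual (BAU) keeps the
current cold-housing exposure; the intervention removes the cold-induced SBP
elevation from the exposed, which lowers disease incidence through per-year
population impact fractions.  Disease-specific mortality and morbidity
differences feed back into the main lifetable each cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .disease import TrendSpec, run_disease_trajectory
from .exposure import ScenarioConfig, annual_sbp_shift, pif_shift
from .inputs import (DISEASES, SBP_MIN_AGE, CohortInputs, EpiTable,
                     RiskFunctions, band_midpoint)
from .lifetable import health_adjust, step_main

__all__ = ["RunResult", "run_scenario", "horizon_aggregate",
           "league_table_report", "per_target_population"]


@dataclass(frozen=True)
class RunResult:
    """Per-cohort, per-calendar-year lifetable output of one scenario arm.

    ``lifetable`` columns: sex, age_group (base-year band), year, alive
    (cohort proportion at cycle start), person_years, halys, deaths — the
    last three in absolute person units (scaled by the stratum count).
    """

    mode: str
    lifetable: pd.DataFrame
    config: ScenarioConfig
    total_n: float

    def total_halys(self, horizon="lifetime", rate: float = 0.0) -> float:
        return horizon_aggregate(self, horizon, rate)["total"]

    def per_1000(self, horizon="lifetime", rate: float = 0.0) -> float:
        return horizon_aggregate(self, horizon, rate)["per_1000"]


def _pif_series(cohort: CohortInputs, risks: RiskFunctions | None,
                disease: str, delta: float, a0: float, n_years: int) -> np.ndarray:
    pifs = np.zeros(n_years)
    if risks is None or delta <= 0.0 or cohort.exposure_prev <= 0.0:
        return pifs
    for y in range(n_years):
        if a0 + y + 0.5 < SBP_MIN_AGE:
            continue  # no measured SBP below 15: no modelled pathway
        beta = risks.beta_for_cycle(disease, a0, y)
        if beta > 0.0:
            pifs[y] = pif_shift(cohort.exposure_prev, delta, beta)
    return pifs


def _run_cohort(table: EpiTable, risks: RiskFunctions | None,
                cfg: ScenarioConfig, cohort: CohortInputs,
                intervention: bool) -> pd.DataFrame:
    a0 = band_midpoint(cohort.age_group)
    n_years = math.ceil(cfg.max_age - a0)
    trend = TrendSpec(cfg.incidence_apc, cfg.case_fatality_apc)
    delta = annual_sbp_shift(cfg) if intervention else 0.0

    dmort = np.zeros(n_years)
    dyld = np.zeros(n_years)
    if intervention and delta > 0.0:
        for d in DISEASES:
            pifs = _pif_series(cohort, risks, d, delta, a0, n_years)
            if not pifs.any():
                continue  # no pathway: the disease cancels exactly in the deltas
            zero = np.zeros(n_years)
            bau = run_disease_trajectory(table, cohort, d, zero, trend, n_years)
            scn = run_disease_trajectory(table, cohort, d, pifs, trend, n_years)
            dmort += scn.mortality - bau.mortality
            dyld += scn.yld - bau.yld

    l = 1.0
    rows = np.empty((n_years, 5))
    for y in range(n_years):
        acmr, yld_prop, _ = table.cycle_rates(cohort.sex, a0, y)
        m = acmr * (1.0 + cfg.acmr_apc) ** y
        l_next, L, deaths = step_main(l, m, dmort[y])
        haly = health_adjust(L, yld_prop, dyld[y])
        rows[y] = (cfg.base_year + y, l, L, haly, deaths)
        l = l_next

    df = pd.DataFrame(rows, columns=["year", "alive", "person_years",
                                     "halys", "deaths"])
    df["year"] = df["year"].astype(int)
    for col in ("person_years", "halys", "deaths"):
        df[col] *= cohort.n
    df.insert(0, "age_group", cohort.age_group)
    df.insert(0, "sex", cohort.sex)
    return df


def run_scenario(table: EpiTable, risks: RiskFunctions | None,
                 cfg: ScenarioConfig, mode: str) -> RunResult:
    """Run one arm ("bau" or "intervention") across all cohorts.

    Deterministic given the configuration (central parameter values, no
    sampling).  The BAU arm is by construction invariant to the risk
    functions and the scenario temperature fields.
    """
    if mode not in ("bau", "intervention"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "intervention" and risks is None:
        raise ValueError("intervention mode requires risk functions")
    frames = [_run_cohort(table, risks, cfg, cohort, mode == "intervention")
              for cohort in table.strata]
    lifetable = pd.concat(frames, ignore_index=True)
    return RunResult(mode=mode, lifetable=lifetable, config=cfg,
                     total_n=table.total_n)


def _horizon_mask(years: pd.Series, horizon, base_year: int) -> pd.Series:
    if horizon == "lifetime":
        return pd.Series(True, index=years.index)
    if isinstance(horizon, (int, np.integer)):
        return (years >= base_year) & (years < base_year + int(horizon))
    raise ValueError(f"unknown horizon {horizon!r}")


def horizon_aggregate(result: RunResult, horizon, rate: float = 0.0,
                      value_col: str = "halys") -> dict:
    """Sum (discounted) HALYs over calendar years [base, base+horizon).

    ``horizon`` is 10, 20 or "lifetime" (all simulated years, half-open
    windows).  Returns ``{"total": ..., "per_1000": ...}``.
    """
    df = result.lifetable
    base = result.config.base_year
    mask = _horizon_mask(df["year"], horizon, base)
    sub = df.loc[mask, ["year", value_col]]
    factors = (1.0 + rate) ** -(sub["year"] - base)
    total = float((sub[value_col] * factors).sum())
    return {"total": total, "per_1000": total / (result.total_n / 1000.0)}


def per_target_population(per_1000_gain: float, exposed_share: float) -> float:
    """Rescale a whole-population per-1000 gain to the exposed (target)
    population: gain / exposed share."""
    if not (0.0 < exposed_share <= 1.0):
        raise ValueError("exposed_share must be in (0, 1]")
    return per_1000_gain / exposed_share


def league_table_report(estimate: float, lo: float | None, hi: float | None,
                        comparators: pd.DataFrame | None = None,
                        name: str = "Eradication of cold housing") -> pd.DataFrame:
    """Insert the model's discounted per-1000 HALY estimate into a
    user-supplied league table of interventions.

    ``comparators`` columns: intervention, halys_per_1000, ui_lo, ui_hi.
    Rows are ordered by descending HALYs per 1000, ties broken by name.
    """
    rows = [{"intervention": name, "halys_per_1000": estimate,
             "ui_lo": lo, "ui_hi": hi}]
    if comparators is not None and len(comparators):
        required = {"intervention", "halys_per_1000"}
        missing = required - set(comparators.columns)
        if missing:
            raise ValueError(f"comparator table missing columns: {missing}")
        rows.extend(comparators.to_dict("records"))
    df = pd.DataFrame(rows, columns=["intervention", "halys_per_1000",
                                     "ui_lo", "ui_hi"])
    df = df.sort_values(["halys_per_1000", "intervention"],
                        ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)
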