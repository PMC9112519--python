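"""Model/Results interface to the proportional multistate lifetable.

:class:`PMSLT` bundles the base-year epidemiological table, the SBP
relative-risk functions and a scenario configuration; :meth:`PMSLT.fit`
simulates business as usual and the cold-housing-eradication intervention
and returns a :class:`PMSLTResults` carrying the per-year lifetables, the
health-adjusted life years gained by horizon and discount rate, and (when
Monte Carlo iterations are requested) 95% uncertainty intervals.

Example
-------
>>> from pmslt import PMSLT
>>> res = PMSLT.from_packaged_data().fit()
>>> res.per_1000_gain("lifetime", 0.0)            # doctest: +SKIP
>>> print(res.summary())                          # doctest: +SKIP
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (RunResult, horizon_aggregate, league_table_report,
                     per_target_population, run_scenario)
from .exposure import ScenarioConfig, annual_sbp_shift, pif_shift
from .inputs import (DISEASES, SBP_MIN_AGE, EpiTable, RiskFunctions,
                     band_midpoint, load_cohort_inputs, load_risk_functions,
                     packaged_cohort_inputs, packaged_risk_functions)
from .uncertainty import MonteCarloResult, UncertaintySpec, run_monte_carlo

__all__ = ["PMSLT", "PMSLTResults"]


class PMSLT:
    """Proportional multistate lifetable model of cold-housing eradication.

    Parameters
    ----------
    table : EpiTable
        Base-year sex x age-band epidemiological inputs.
    risks : RiskFunctions, optional
        SBP-to-disease relative risks; required to simulate the intervention.
    config : ScenarioConfig, optional
        Scenario definition (defaults encode the study scenario).
    """

    def __init__(self, table: EpiTable, risks: RiskFunctions | None = None,
                 config: ScenarioConfig | None = None):
        self.table = table
        self.risks = risks
        self.config = config or ScenarioConfig()

    @classmethod
    def from_csv(cls, inputs_path, risks_path=None, config=None) -> "PMSLT":
        table = load_cohort_inputs(inputs_path)
        risks = load_risk_functions(risks_path) if risks_path else None
        if isinstance(config, (str, Path)):
            config = ScenarioConfig.from_yaml(config)
        return cls(table, risks, config)

    @classmethod
    def from_packaged_data(cls, config: ScenarioConfig | None = None) -> "PMSLT":
        return cls(packaged_cohort_inputs(), packaged_risk_functions(), config)

    @property
    def exposed_share(self) -> float:
        """Exposed (cold-housing) share used for per-target-population
        reporting: the configured override if any, else the population-
        weighted mean of the table's prevalences."""
        if self.config.exposed_share_override is not None:
            return self.config.exposed_share_override
        return self.table.exposed_share

    def fit(self, iterations: int | None = None, seed: int | None = None,
            uncertainty_spec: UncertaintySpec | None = None) -> "PMSLTResults":
        """Run BAU (and, when risks are present, the intervention).

        ``iterations`` > 0 additionally runs the Monte Carlo uncertainty
        analysis with the given ``seed``.
        """
        bau = run_scenario(self.table, self.risks, self.config, "bau")
        scenario = None
        if self.risks is not None:
            scenario = run_scenario(self.table, self.risks, self.config,
                                    "intervention")
        mc = None
        if iterations:
            if self.risks is None:
                raise ValueError("uncertainty analysis requires risk functions")
            mc = run_monte_carlo(self.table, self.risks, self.config,
                                 uncertainty_spec, iterations, seed)
        return PMSLTResults(self, bau, scenario, mc)

    def pif_table(self) -> pd.DataFrame:
        """Per (sex, base-year band, disease, year) population impact
        fractions under the central scenario."""
        delta = annual_sbp_shift(self.config)
        rows = []
        for cohort in self.table.strata:
            a0 = band_midpoint(cohort.age_group)
            n_years = math.ceil(self.config.max_age - a0)
            for d in DISEASES:
                for y in range(n_years):
                    beta = (self.risks.beta_for_cycle(d, a0, y)
                            if self.risks is not None
                            and a0 + y + 0.5 >= SBP_MIN_AGE
                            else 0.0)
                    pif = (pif_shift(cohort.exposure_prev, delta, beta)
                           if beta > 0 else 0.0)
                    rows.append((cohort.sex, cohort.age_group, d,
                                 self.config.base_year + y, pif))
        return pd.DataFrame(rows, columns=["sex", "age_group", "disease",
                                           "year", "pif"])


class PMSLTResults:
    """Results of a fitted :class:`PMSLT` run."""

    def __init__(self, model: PMSLT, bau: RunResult,
                 scenario: RunResult | None,
                 uncertainty: MonteCarloResult | None = None):
        self.model = model
        self.config = model.config
        self.bau = bau
        self.scenario = scenario
        self.uncertainty = uncertainty

    # -- core reporting -------------------------------------------------

    def _require_scenario(self) -> RunResult:
        if self.scenario is None:
            raise ValueError("model was fitted without risk functions; "
                             "no intervention arm available")
        return self.scenario

    def haly_gain(self, horizon="lifetime", discount: float = 0.0) -> float:
        """Total HALYs gained (intervention - BAU) over a horizon."""
        scn = self._require_scenario()
        return (horizon_aggregate(scn, horizon, discount)["total"]
                - horizon_aggregate(self.bau, horizon, discount)["total"])

    def per_1000_gain(self, horizon="lifetime", discount: float = 0.0) -> float:
        return self.haly_gain(horizon, discount) / (self.bau.total_n / 1000.0)

    def bau_per_1000(self, horizon="lifetime", discount: float = 0.0) -> float:
        return horizon_aggregate(self.bau, horizon, discount)["per_1000"]

    def per_1000_exposed_gain(self, horizon="lifetime", discount: float = 0.0,
                              exposed_share: float | None = None) -> float:
        """Gain per 1000 persons of the exposed (target) population."""
        share = self.model.exposed_share if exposed_share is None else exposed_share
        return per_target_population(self.per_1000_gain(horizon, discount), share)

    def conf_int(self, horizon="lifetime", discount: float = 0.0) -> tuple[float, float]:
        """95% uncertainty interval of the per-1000 gain (requires a Monte
        Carlo fit)."""
        if self.uncertainty is None:
            raise ValueError("fit with iterations= to obtain uncertainty intervals")
        cell = (horizon, discount)
        return (self.uncertainty.lo[cell], self.uncertainty.hi[cell])

    @property
    def lifetable(self) -> pd.DataFrame:
        """Merged per-cohort, per-year lifetable of both arms."""
        bau = self.bau.lifetable.rename(columns={
            "alive": "alive_bau", "person_years": "L_bau",
            "halys": "haly_bau", "deaths": "deaths_bau"})
        if self.scenario is None:
            return bau
        scn = self.scenario.lifetable.rename(columns={
            "alive": "alive_int", "person_years": "L_int",
            "halys": "haly_int", "deaths": "deaths_int"})
        merged = bau.merge(scn, on=["sex", "age_group", "year"])
        merged["haly_gain"] = merged["haly_int"] - merged["haly_bau"]
        return merged

    def gain_table(self) -> pd.DataFrame:
        """HALY gains (total and per 1000) for every horizon x discount cell."""
        rows = []
        for horizon in self.config.horizons:
            for rate in self.config.discount_rates:
                row = {"horizon": horizon, "discount_rate": rate,
                       "bau_per_1000": self.bau_per_1000(horizon, rate)}
                if self.scenario is not None:
                    row["haly_gain"] = self.haly_gain(horizon, rate)
                    row["gain_per_1000"] = self.per_1000_gain(horizon, rate)
                    if self.uncertainty is not None:
                        lo, hi = self.conf_int(horizon, rate)
                        row["ui_lo_per_1000"], row["ui_hi_per_1000"] = lo, hi
                rows.append(row)
        return pd.DataFrame(rows)

    def league_table(self, comparators: pd.DataFrame | None = None,
                     horizon="lifetime", discount: float = 0.03) -> pd.DataFrame:
        lo = hi = None
        if self.uncertainty is not None:
            lo, hi = self.conf_int(horizon, discount)
        return league_table_report(self.per_1000_gain(horizon, discount),
                                   lo, hi, comparators)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Proportional multistate lifetable: cold-housing eradication",
            "=" * 62,
            f"Population (base year {cfg.base_year}): {self.bau.total_n:,.0f}",
            f"Exposed share used for target-population scaling: "
            f"{self.model.exposed_share:.4f}",
            f"Annualised SBP reduction for the exposed: "
            f"{annual_sbp_shift(cfg):.3f} mmHg",
            f"Config hash: {cfg.config_hash()}",
            "",
            self.gain_table().to_string(index=False, float_format=lambda v: f"{v:,.3f}"),
        ]
        if self.uncertainty is not None:
            lines += ["", f"Monte Carlo: {self.uncertainty.iterations} iterations, "
                          f"seed={self.uncertainty.seed}, "
                          f"redraws={self.uncertainty.redraws}"]
        return "\n".join(lines)

    def plot(self, ax=None, discount: float = 0.0):
        """Cumulative HALY gain by calendar year."""
        import matplotlib.pyplot as plt

        self._require_scenario()
        df = self.lifetable
        yearly = df.groupby("year")["haly_gain"].sum()
        factors = (1.0 + discount) ** -(yearly.index - self.config.base_year)
        cum = (yearly * factors).cumsum()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(cum.index, cum.values)
        ax.set_xlabel("calendar year")
        ax.set_ylabel("cumulative HALYs gained")
        ax.set_title(f"Cold-housing eradication (discount {discount:.0%})")
        return ax

    def to_files(self, outdir) -> None:
        """Write results.json, lifetable.csv and pif.csv to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.lifetable.to_csv(outdir / "lifetable.csv", index=False)
        self.model.pif_table().to_csv(outdir / "pif.csv", index=False)
        payload = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "population": self.bau.total_n,
            "exposed_share": self.model.exposed_share,
            "cells": json.loads(
                self.gain_table().to_json(orient="records")),
        }
        if self.uncertainty is not None:
            payload["monte_carlo"] = {
                "iterations": self.uncertainty.iterations,
                "seed": self.uncertainty.seed,
                "redraws": self.uncertainty.redraws,
            }
        (outdir / "results.json").write_text(json.dumps(payload, indent=2))
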