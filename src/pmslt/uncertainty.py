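"""Monte Carlo propagation of parameter uncertainty.

One coherent joint draw perturbs: the exposure-time fraction
(Beta(10.5, 22)), the trial SBP effect (normal, sd from its 95% CI), the
age-specific cold-housing prevalence (normal, sd = 2 x survey standard
error, exchangeable cross-age correlation 0.1574, identical draws for both
sexes), disease incidence and case fatality (lognormal multipliers, 5%
log-scale sd, shared between sexes per disease), disability rates (normal
multipliers, 10% sd) and the SBP relative risks (lognormal within their
published CIs, one deviate per disease).  Invalid draws (rates < 0,
prevalence outside [0, 1]) are rejected and redrawn; 95% uncertainty
intervals are the 2.5th/97.5th empirical percentiles across iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import horizon_aggregate, run_scenario
from .exposure import ScenarioConfig
from .inputs import AGE_BANDS, DISEASES, EpiTable, RiskFunctions

__all__ = ["UncertaintySpec", "Draw", "sample_draw", "run_monte_carlo",
           "MonteCarloResult"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class UncertaintySpec:
    """Distributional assumptions for the probabilistic analysis."""

    incidence_log_sd: float = 0.05
    case_fatality_log_sd: float = 0.05
    disability_sd: float = 0.10
    #: multiplier on the survey standard error of exposure prevalence.
    prevalence_se_scale: float = 2.0
    #: exchangeable pairwise correlation of prevalence across age bands.
    prevalence_corr: float = 0.1574
    #: households in the housing-conditions survey, split evenly over bands
    #: to form binomial standard errors.
    survey_households: int = 4500
    #: sd of the trial SBP effect, from its 95% CI (-9.3, -2.4) mmHg.
    sbp_effect_sd: float = (9.3 - 2.4) / (2 * _Z95)
    use_rr_ci: bool = True
    #: draw the exposure-time fraction from its Beta distribution; when off
    #: the central fraction is used in every iteration.
    sample_exposure_time: bool = True
    max_redraws: int = 1000

    def zeroed(self) -> "UncertaintySpec":
        """All-sds-zero copy (degenerate draws equal the central values)."""
        return replace(self, incidence_log_sd=0.0, case_fatality_log_sd=0.0,
                       disability_sd=0.0, prevalence_se_scale=0.0,
                       sbp_effect_sd=0.0, use_rr_ci=False,
                       sample_exposure_time=False)


@dataclass(frozen=True)
class Draw:
    """One joint parameter draw."""

    table: EpiTable
    risks: RiskFunctions | None
    config: ScenarioConfig
    redraws: int


def _prevalence_cov(p: np.ndarray, spec: UncertaintySpec) -> np.ndarray:
    n_per_band = spec.survey_households / len(AGE_BANDS)
    se = np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / n_per_band)
    sd = spec.prevalence_se_scale * se
    corr = np.full((len(p), len(p)), spec.prevalence_corr)
    np.fill_diagonal(corr, 1.0)
    return np.outer(sd, sd) * corr


def _draw_prevalence(p: np.ndarray, spec: UncertaintySpec,
                     rng: np.random.Generator) -> tuple[np.ndarray, int]:
    if spec.prevalence_se_scale == 0.0:
        return p.copy(), 0
    cov = _prevalence_cov(p, spec)
    # tiny jitter keeps the exchangeable matrix positive definite at corr ~ 1
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(len(p)))
    for attempt in range(spec.max_redraws):
        draw = p + chol @ rng.standard_normal(len(p))
        if ((draw >= 0.0) & (draw <= 1.0)).all():
            return draw, attempt
    return np.clip(draw, 0.0, 1.0), spec.max_redraws


def _positive_normal(centre: float, sd: float, rng: np.random.Generator,
                     max_redraws: int) -> tuple[float, int]:
    if sd == 0.0:
        return centre, 0
    for attempt in range(max_redraws):
        v = rng.normal(centre, sd)
        if v >= 0.0:
            return v, attempt
    return 0.0, max_redraws


def _perturb_risks(risks: RiskFunctions, z: Mapping[str, float],
                   spec: UncertaintySpec) -> RiskFunctions:
    rr = {}
    for (d, b), v in risks.rr.items():
        sd = 0.0
        if spec.use_rr_ci and (d, b) in risks.ci:
            lo, hi = risks.ci[(d, b)]
            sd = (math.log(hi) - math.log(lo)) / (2 * _Z95)
        rr[(d, b)] = v * math.exp(z.get(d, 0.0) * sd)
    return RiskFunctions(rr=rr, ci=risks.ci, source=risks.source)


def sample_draw(table: EpiTable, risks: RiskFunctions | None,
                cfg: ScenarioConfig, spec: UncertaintySpec,
                rng: np.random.Generator) -> Draw:
    """Draw one coherent set of perturbed model inputs.

    Deterministic given the generator state.  Between-sex correlation 1.0 is
    implemented by sharing deviates across sexes; the cross-age prevalence
    correlation uses a Gaussian copula with an exchangeable structure.
    """
    redraws = 0

    if spec.sample_exposure_time:
        tf = float(rng.beta(cfg.exposure_time_alpha1, cfg.exposure_time_alpha2))
    else:
        tf = cfg.central_time_fraction
    effect, r = _positive_normal(cfg.sbp_effect_mmhg, spec.sbp_effect_sd,
                                 rng, spec.max_redraws)
    redraws += r
    cfg_draw = cfg.with_(exposure_time_fraction=tf, sbp_effect_mmhg=effect)

    # one prevalence draw per age band, shared by both sexes
    central_prev = np.array(
        [table.stratum("male", b).exposure_prev for b in AGE_BANDS])
    prev_draw, r = _draw_prevalence(central_prev, spec, rng)
    redraws += r
    prev_by_band = dict(zip(AGE_BANDS, prev_draw))

    inc_mult, cfr_mult, dr_mult, rr_z = {}, {}, {}, {}
    for d in DISEASES:
        inc_mult[d] = math.exp(rng.standard_normal() * spec.incidence_log_sd)
        cfr_mult[d] = math.exp(rng.standard_normal() * spec.case_fatality_log_sd)
        dr_mult[d], r = _positive_normal(1.0, spec.disability_sd, rng,
                                         spec.max_redraws)
        redraws += r
        rr_z[d] = float(rng.standard_normal())

    strata = []
    for s in table.strata:
        diseases = {
            d: replace(rates,
                       incidence=rates.incidence * inc_mult[d],
                       case_fatality=rates.case_fatality * cfr_mult[d],
                       disability=rates.disability * dr_mult[d])
            for d, rates in s.diseases.items()
        }
        strata.append(replace(s, exposure_prev=prev_by_band[s.age_group],
                              diseases=diseases))
    table_draw = EpiTable(strata)

    risks_draw = None
    if risks is not None:
        risks_draw = _perturb_risks(risks, rr_z, spec)
    return Draw(table=table_draw, risks=risks_draw, config=cfg_draw,
                redraws=redraws)


@dataclass(frozen=True)
class MonteCarloResult:
    """Central estimate plus empirical percentile intervals per reporting
    cell (horizon x discount rate), in HALYs gained per 1000 persons."""

    cells: tuple
    central: Mapping
    draws: pd.DataFrame
    iterations: int
    seed: int | None
    redraws: int

    def percentile(self, q: float) -> Mapping:
        return {c: float(np.percentile(self.draws[str(c)], q)) for c in self.cells}

    @property
    def lo(self) -> Mapping:
        return self.percentile(2.5)

    @property
    def hi(self) -> Mapping:
        return self.percentile(97.5)

    @property
    def mean(self) -> Mapping:
        return {c: float(self.draws[str(c)].mean()) for c in self.cells}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        lo, hi, mean = self.lo, self.hi, self.mean
        for c in self.cells:
            horizon, rate = c
            rows.append({"horizon": horizon, "discount_rate": rate,
                         "central": self.central[c], "mean": mean[c],
                         "ui_lo": lo[c], "ui_hi": hi[c]})
        return pd.DataFrame(rows)


def _gain_cells(table, risks, cfg) -> dict:
    bau = run_scenario(table, risks, cfg, "bau")
    scn = run_scenario(table, risks, cfg, "intervention")
    out = {}
    for horizon in cfg.horizons:
        for rate in cfg.discount_rates:
            g = (horizon_aggregate(scn, horizon, rate)["per_1000"]
                 - horizon_aggregate(bau, horizon, rate)["per_1000"])
            out[(horizon, rate)] = g
    return out


def run_monte_carlo(table: EpiTable, risks: RiskFunctions,
                    cfg: ScenarioConfig, spec: UncertaintySpec | None = None,
                    iterations: int | None = None,
                    seed: int | None = None) -> MonteCarloResult:
    """Propagate parameter uncertainty through the full model.

    Runs the central-parameter scenario once, then ``iterations`` independent
    joint draws, recording per-1000 HALY gains for every horizon x discount
    cell.  Reproducible given ``seed``.
    """
    spec = spec or UncertaintySpec()
    iterations = cfg.iterations if iterations is None else int(iterations)
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    central = _gain_cells(table, risks, cfg)
    cells = tuple(central)
    records, redraws = [], 0
    for _ in range(iterations):
        draw = sample_draw(table, risks, cfg, spec, rng)
        redraws += draw.redraws
        gains = _gain_cells(draw.table, draw.risks, draw.config)
        records.append({str(c): gains[c] for c in cells})
    draws = pd.DataFrame.from_records(records)
    return MonteCarloResult(cells=cells, central=central, draws=draws,
                            iterations=iterations, seed=seed, redraws=redraws)
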