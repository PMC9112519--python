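# pmslt — cardiovascular health gains from eradicating cold housing

A proportional multistate lifetable (pMSLT) model of the cardiovascular
health gains achievable by permanently warming cold homes (assumed average
indoor temperature 16 °C) to 20 °C, for the 2016 population of three
Australian states.  It is written for epidemiologists and health-economic
modellers who want a transparent, scriptable implementation of the
cold → systolic blood pressure → cardiovascular disease causal chain with
full Monte Carlo uncertainty propagation.

## The model

The 2016 population is simulated as 42 closed sex × 5-year-age-band cohorts
in annual cycles until each cohort reaches age 110.  Three diseases —
ischemic heart disease, ischemic stroke and haemorrhagic stroke — run as
independent three-state lifetables (healthy *S*, diseased *C*, dead from
disease *D*) with the exact constant-rate cycle solution

    S' = S e^{-i},   C' = C e^{-f} + i S (e^{-i} - e^{-f})/(f - i),

where *i* is incidence and *f* case fatality (no remission).  A main
lifetable carries all-cause mortality *m* and morbidity (the YLD proportion
of a life year); each cycle it absorbs the summed disease-specific mortality
and morbidity differences Δm and Δyld between the two arms:

    l' = l e^{-(m + Δm)},   HALY = ½(l + l') (1 - (yld + Δyld)).

The intervention removes an annualised systolic-blood-pressure elevation

    δ = time_fraction × (20 − 16) °C × (5.8 mmHg / 10 °C)

from the exposed (cold-housing) fraction π of each cohort, where the
exposure-time fraction of the year follows Beta(10.5, 22) and 5.8 mmHg is
the trial effect over a 10 °C contrast.  Under GBD-style log-linear relative
risks RR(x) = e^{βx} this shift becomes a population impact fraction on
incidence,

    PIF = π (e^{βδ} − 1) / (π e^{βδ} + 1 − π),

applied per disease, per attained-age band, from age 15 up.  Outputs are
health-adjusted life years (HALYs) gained versus business as usual, total
and per 1000 persons alive in 2016, over 10-year, 20-year and lifetime
horizons at 0% and 3% discount rates, with 95% uncertainty intervals from
Monte Carlo draws of all major inputs.

The base-year epidemiological table is packaged
(`pmslt/data/table2_2016.csv`).  The packaged SBP relative-risk table
(`risk_functions_sbp_synthetic.csv`) is a clearly labelled synthetic
stand-in with GBD-style age-declining RRs; substitute the published
supplementary values via `PMSLT.from_csv(..., risks_path=...)` for exact
reproduction.

## Worked example

```python
from pmslt import PMSLT

res = PMSLT.from_packaged_data().fit(iterations=200, seed=1)
print(res.summary())
```

```
Proportional multistate lifetable: cold-housing eradication
==============================================================
Population (base year 2016): 15,560,018
Exposed share used for target-population scaling: 0.0749
Annualised SBP reduction for the exposed: 0.750 mmHg
Config hash: 7c5fc95962ab

 horizon  discount_rate  bau_per_1000  haly_gain  gain_per_1000  ui_lo_per_1000  ui_hi_per_1000
      10          0.000     8,230.675    262.469          0.017           0.004           0.039
      10          0.030     7,251.383    214.569          0.014           0.003           0.032
      20          0.000    15,511.724  1,790.151          0.115           0.023           0.263
      20          0.030    12,028.085  1,185.924          0.076           0.015           0.174
lifetime          0.000    36,652.491 39,138.271          2.515           0.622           5.907
lifetime          0.030    18,974.841  9,792.983          0.629           0.139           1.436

Monte Carlo: 200 iterations, seed=1, redraws=183
```

Reading the table: under business as usual the population accrues about
36,652 undiscounted HALYs per 1000 persons over its remaining lifetime;
eradicating cold housing adds a central 2.52 HALYs per 1000 (95% UI
0.62–5.91), of which 0.115 arrives in the first twenty years.  Dividing by
the exposed share gives the gain per 1000 people actually living in cold
housing (`res.per_1000_exposed_gain()` ≈ 33.6).  Note the lifetime figures
assume disease rates frozen at base-year levels; a secular decline in CVD
incidence/case fatality (configurable via `incidence_apc` /
`case_fatality_apc`) lowers them substantially — see `docs/methods.md`.

The same run from a shell:

```sh
pmslt run --inputs table2.csv --risks rr.csv --mode both \
      --iterations 200 --seed 1 --out results/
pmslt synth --out synth_inputs.csv     # synthetic table with known truth
pmslt check --inputs table2.csv        # epidemiological coherence report
```

## Layout

* `pmslt.inputs` — input tables, validation, unit conversion, coherence checks
* `pmslt.disease` / `pmslt.lifetable` — disease and main lifetable cycles
* `pmslt.exposure` — scenario configuration, SBP shift, impact fractions
* `pmslt.engine` / `pmslt.model` — scenario orchestration and the
  `PMSLT` / `PMSLTResults` interface
* `pmslt.uncertainty` — correlated Monte Carlo input sampling
* `pmslt.synthetic` — synthetic data with closed-form oracles
* `pmslt.cli` — the `pmslt` command
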