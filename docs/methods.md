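# Methods

## Model structure

The package implements a proportional multistate lifetable (pMSLT): a main
cohort lifetable coupled to parallel disease-specific three-state lifetables
whose mortality and morbidity *differences* between two arms (business as
usual vs intervention) feed back into the main table each annual cycle.
The 42 base-year strata (male/female × 5-year bands 0–4 … 100–104) are
treated as closed cohorts aging together from their mid-band age; there is
no fertility, migration, or interaction between diseases (parallel
lifetables), and stroke subtypes run separately.

**Disease cycles.** Within a cycle rates are constant and the system
dS/dt = −iS, dC/dt = iS − fC, dD/dt = fC is solved exactly (matrix
exponential in closed form; the f = i limit is taken when |f − i| < 1e-9).
Mass is conserved to < 1e-12 per cycle by accumulating deaths as
(S − S′) + (C − C′).  Remission is zero for all three conditions, the
standard chronic-CVD convention.  Initial diseased proportions are seeded
from the turnover steady state i/(i+f) implied by the base-year rates;
an explicit `initial_prevalence` argument overrides this when prevalence
data are available.  Because the intervention acts through *differences*
between arms, the seeding choice largely cancels in the reported gains.

**Main lifetable.** Rates are hazards with exponential within-cycle
survival; person-years use the mid-cycle (trapezoid) approximation
L = (l + l′)/2; health-adjusted person-years multiply L by one minus the
morbidity proportion (all-cause YLD proportion plus the summed disease YLD
difference, clamped to [0, 1] with a warning).  Discounting divides each
calendar year's value by (1+r)^(year − 2016), the base year undiscounted.

**Age-band blending.** Cohorts start mid-band, so an annual cycle can
straddle a 5-year band boundary.  Rates for such a cycle are the
time-weighted blend of the two bands (weights = overlap of the cycle's age
interval with each band).  Assigning whole cycles to a single band instead
shifts every band window by half a year and biased life expectancy in the
synthetic Gompertz check by ~0.8%; with blending the engine reproduces the
closed-form life expectancy of its input hazard schedule to < 0.01%.
Rates of the 100–104 band are carried forward to the simulation ceiling of
age 110 (the table repeats the 95–99 values at 100–104, implying rate
carry-forward at the tail).

## Intervention and impact fractions

The scenario lifts cold homes from 16 °C to 20 °C.  The trial evidence is a
5.8 mmHg systolic difference over a 10 °C contrast, linearised to
0.58 mmHg/°C.  Occupants are exposed for a Beta(α₁=10.5, α₂=22) fraction of
the year (median 0.319, 95% central range 0.176–0.490), so the annualised
mean SBP reduction for the exposed is δ = fraction × 4 × 0.58 ≈ 0.75 mmHg
centrally.  The central run uses the Beta mean (0.323); the Monte Carlo
samples the full distribution.

The reduction converts to a population impact fraction per disease and
attained-age band with the two-group shift formula
PIF = π(e^{βδ} − 1)/(πe^{βδ} + 1 − π), where β = ln(RR per 10 mmHg)/10 and
the unexposed are the reference.  This treats the recorded SBP distribution
as already containing the cold-induced elevation in the exposed; the
distributional variant (`pif_distributional`) exposes the alternative
convention (elevation added on top of recorded SBP) as a flag — under
log-linear RRs that alternative reduces to π(1 − e^{−βδ}) and the choice of
risk-reference level (TMREL) cancels in both.  PIFs apply to incidence
only, never case fatality; ages below 15 (no measured SBP) and bands below
a disease's youngest RR entry contribute no impact fraction.  Exposure
prevalence is the cohort's base-year value, held constant for life.

The packaged relative-risk table is a **synthetic stand-in** (log-linear-
in-age declining RRs per 10 mmHg, e.g. IHD 1.60 at 55–59 falling to ~1.1 at
100+, steeper for the strokes), chosen once from the comparative-risk-
assessment literature; users with access to the study's supplementary
age-specific RRs should supply them as a CSV.

## Trends and horizons

Annual percentage changes (APC) in incidence and case fatality are
configurable per disease and default to **0** (no secular trend); all-cause
mortality is likewise held at base-year levels.  This is the dominant
structural lever for lifetime results: with defaults the model yields a
central 2.52 undiscounted lifetime HALYs gained per 1000 persons, whereas a
plausible −1%/yr decline in CVD incidence and case fatality yields 1.46 and
roughly doubles the share of the gain arriving in the first 20 years (from
~5% to ~7%).  Lifetime means until cohort extinction at age 110 (year 2126
for the youngest cohort); 10- and 20-year horizons are half-open calendar
windows [2016, 2026) and [2016, 2036).

## Uncertainty analysis

Each Monte Carlo iteration makes one coherent joint draw:

* exposure-time fraction ~ Beta(10.5, 22);
* trial SBP effect ~ Normal(5.8, 1.76) mmHg, the sd from its 95% CI
  (−9.3, −2.4), redrawn if negative;
* cold-housing prevalence per age band ~ Normal with sd = 2 × binomial
  survey SE (4,500 households split evenly over the 21 bands), exchangeable
  cross-age correlation 0.1574 via a Gaussian copula, identical draws for
  both sexes;
* incidence and case-fatality multipliers ~ lognormal with 5% log-scale sd,
  one per disease shared across ages and sexes (between-sex correlation 1);
* disability-rate multipliers ~ Normal(1, 0.10), redrawn if negative;
* relative risks ~ lognormal within their published CI per disease.

Invalid draws are rejected and redrawn (preserving distribution shape away
from the boundary) up to a retry cap, then clipped; both are counted and
reported.  Intervals are the empirical 2.5th/97.5th percentiles of per-1000
gains across iterations; both the central-parameter run and the across-draw
mean are reported, since either could serve as the point estimate.  The
default iteration count is 2000; the acceptance script and tests use 200,
which resolves the interval endpoints to well within their Monte Carlo
noise for qualitative statements (width, right skew) while keeping runtimes
under a minute.

## Synthetic data

The generator emulates the *statistical shape* of the base-year table:
Gompertz all-cause mortality (band values are exact within-band averages of
the continuous hazard, so the discrete lifetable tracks the continuous
survival curve at band edges), log-linear-in-age disease incidence,
morbidity proportions rising linearly with age, normal SBP from age 15, and
exposure prevalence declining with age.  It does **not** emulate survey
design, within-band heterogeneity, cohort effects, or correlated
measurement error, so tests passing on synthetic data validate the
arithmetic and plumbing, not the realism of any particular input set.
`known_truth_experiment` rebuilds a single constant-rate cohort and
recomputes its HALY gain through an independent route (scipy matrix
exponentials plus straight-line lifetable arithmetic), requiring agreement
to 1e-6 relative.

## Numerical choices and degenerate inputs

* f = i tolerance 1e-9 in the disease cycle; quadrature for the
  distributional PIF at relative tolerance ~1e-10 over ±12 sd.
* Negative total mortality (m + Δm < 0) raises an error — it signals
  disease inputs inconsistent with the all-cause rate.
* Empty tables, missing strata, duplicate strata, negative rates and
  out-of-range prevalences are rejected at load with the row and column
  named.  The coherence report (never mutating) flags strata whose implied
  steady-state CVD mortality exceeds the all-cause rate — true of three
  middle-aged male strata in the packaged table, reflecting the steady-state
  approximation rather than impossible data — and disability weights > 1.
* League-table ranking breaks ties by intervention name (documented,
  deterministic).

## Known limitations

Only the blood-pressure pathway to three CVD endpoints is modelled;
respiratory and mental-health effects of cold housing, temperature–mortality
dose-response curves, time lags, cost-effectiveness and equity analyses are
out of scope.  The exposed share used for target-population scaling is the
population-weighted table prevalence (7.49%) by default; a scalar override
(`exposed_share_override`) accommodates alternative weightings.  Lifetime
results are sensitive to the unmodelled secular decline in CVD rates, as
quantified above.
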