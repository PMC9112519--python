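"""Main cohort lifetable arithmetic.

All-cause mortality acts as a hazard with exponential within-cycle survival;
person-years use the mid-cycle (trapezoid) approximation; health-adjusted
person-years subtract the proportionate morbidity (all-cause YLD proportion
plus any disease-specific change fed back from the disease lifetables);
future values discount at a constant annual rate anchored at the base year.
"""

from __future__ import annotations

import math
import warnings

__all__ = ["step_main", "health_adjust", "discount"]


def step_main(l: float, m: float, dm: float = 0.0) -> tuple[float, float, float]:
    """One annual cycle of the main lifetable.

    Parameters
    ----------
    l : alive proportion at the start of the cycle.
    m : all-cause mortality rate (per person-year).
    dm : summed disease mortality difference from the disease lifetables
        (negative under an effective intervention).

    Returns ``(l_next, person_years, deaths)`` with
    ``l_next = l * exp(-(m + dm))`` and person-years ``(l + l_next) / 2``.
    """
    total = m + dm
    if m < 0:
        raise ValueError("mortality rate must be non-negative")
    if total < 0:
        raise ValueError(
            "total mortality rate m + dm is negative; disease inputs are "
            "inconsistent with the all-cause rate")
    l_next = l * math.exp(-total)
    person_years = 0.5 * (l + l_next)
    return l_next, person_years, l - l_next


def health_adjust(person_years: float, yld_prop: float, dyld: float = 0.0) -> float:
    """Health-adjust person-years: ``L * (1 - (yld_prop + dyld))``.

    ``dyld`` is the summed disease YLD-rate difference (<= 0 under an
    intervention that lowers prevalence).  The combined morbidity proportion
    is clamped to [0, 1] with a warning, since removing disease-specific YLD
    can never create negative morbidity.
    """
    morbidity = yld_prop + dyld
    if morbidity < 0.0 or morbidity > 1.0:
        warnings.warn(
            f"morbidity proportion {morbidity:.4f} outside [0, 1]; clamped",
            stacklevel=2)
        morbidity = min(max(morbidity, 0.0), 1.0)
    return person_years * (1.0 - morbidity)


def discount(value: float, year: int, base_year: int, rate: float) -> float:
    """Discount ``value`` accruing in ``year`` back to ``base_year`` at a
    constant annual ``rate`` (the base year itself is undiscounted)."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if year < base_year:
        raise ValueError("cannot discount a year before the base year")
    return value / (1.0 + rate) ** (year - base_year)
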