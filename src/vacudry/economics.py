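"""Techno-economic model of a batch dryer.

Annualizes the dryer's capital cost with a capital recovery factor,
derives unit drying costs from the annual throughput, cascades per-kg
savings to batch / day / year level, and computes an inflation-adjusted
payback period:

    F_c = d(1+d)^τ / ((1+d)^τ − 1)
    C_a = C_ac + C_m − V_a,     C_s = C_a / M_y
    S_kg = SP − C_ds,  S_b = S_kg·M_d,  S_1 = S_d·days
    Ŧ = ln[1 − (C_cc/S_1)(d − i)] / ln((1+i)/(1+d))

Annual throughput is batches/day × batch mass × operating days, with a
configurable number of effective drying minutes per day (default 600).
Values are kept at full precision; round to cents only when reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

__all__ = [
    "EconomicScenario",
    "EconomicResult",
    "capital_recovery_factor",
    "annual_costs",
    "annual_throughput",
    "unit_costs",
    "savings_cascade",
    "payback_period",
    "evaluate_scenario",
]


@dataclass(frozen=True)
class EconomicScenario:
    """Cost assumptions for one batch-dryer scenario.

    Defaults follow a small 300 USD batch dryer financed at 3% interest
    over a 20-year life with 2.5% inflation, 2 kg batches, 350 drying
    days/year and 600 effective drying minutes per day.  ``dried_cost_per_kg``
    short-circuits the fresh-herb cost chain; set it to None and supply
    ``fresh_mass_per_batch_kg`` to use C_dp = C_fd·M_f/M_d instead.
    """

    batch_time_min: float
    capital_cost: float = 300.0
    interest_rate: float = 0.03
    inflation_rate: float = 0.025
    lifespan_years: int = 20
    maintenance_fraction: float = 0.03  # of annual capital cost
    salvage_fraction: float = 0.08  # of annual capital cost
    batch_mass_kg: float = 2.0
    fresh_price_per_kg: float = 2.0
    selling_price_per_kg: float = 5.0
    days_per_year: float = 350.0
    minutes_per_day: float = 600.0
    dried_cost_per_kg: Optional[float] = 4.25
    fresh_mass_per_batch_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.batch_time_min <= 0:
            raise ValueError("batch_time_min must be positive")
        if not (0 <= self.interest_rate < 1 and 0 <= self.inflation_rate < 1):
            raise ValueError("rates must be fractions in [0, 1)")
        if self.lifespan_years < 1:
            raise ValueError("lifespan must be at least 1 year")
        for name in ("capital_cost", "batch_mass_kg", "fresh_price_per_kg",
                     "selling_price_per_kg", "days_per_year", "minutes_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EconomicResult:
    """Full cost/savings/payback cascade for one scenario."""

    recovery_factor: float
    annual_capital_cost: float
    annual_maintenance: float
    annual_salvage: float
    annual_cost: float
    annual_throughput_kg: float
    drying_cost_per_kg: float
    dried_product_cost_per_kg: float
    savings_per_kg: float
    savings_per_batch: float
    savings_per_day: float
    savings_year_1: float
    payback_years: Optional[float]
    payback_months: Optional[float]
    loss_making: bool = False

    def as_dict(self) -> Dict[str, Optional[float]]:
        return dict(self.__dict__)


def capital_recovery_factor(interest_rate: float, lifespan_years: float) -> float:
    """Annuity factor F_c = d(1+d)^τ/((1+d)^τ − 1); limit 1/τ as d → 0."""
    d, tau = float(interest_rate), float(lifespan_years)
    if tau < 1:
        raise ValueError("lifespan must be at least 1 year")
    if d < 0:
        raise ValueError("interest rate must be non-negative")
    if d == 0:
        return 1.0 / tau
    growth = (1.0 + d) ** tau
    return d * growth / (growth - 1.0)


def annual_costs(scenario: EconomicScenario) -> Dict[str, float]:
    """Annualized capital, maintenance, salvage and net cost."""
    fc = capital_recovery_factor(scenario.interest_rate, scenario.lifespan_years)
    cac = scenario.capital_cost * fc
    cm = scenario.maintenance_fraction * cac
    va = scenario.salvage_fraction * cac
    return {
        "recovery_factor": fc,
        "annual_capital_cost": cac,
        "annual_maintenance": cm,
        "annual_salvage": va,
        "annual_cost": cac + cm - va,
    }


def annual_throughput(
    batch_mass_kg: float,
    batch_time_min: float,
    minutes_per_day: float,
    days_per_year: float,
) -> float:
    """Dried product per year: (minutes/day ÷ batch time) × batch mass × days.

    Fractional batches per day are allowed.
    """
    if batch_time_min <= 0:
        raise ValueError("batch_time_min must be positive")
    return (minutes_per_day / batch_time_min) * batch_mass_kg * days_per_year


def unit_costs(
    scenario: EconomicScenario, annual_cost: float, throughput_kg: float
) -> Dict[str, float]:
    """Per-kg cost chain: C_s = C_a/M_y, C_ds = C_dp + C_s, S_kg = SP − C_ds.

    When the scenario fixes ``dried_cost_per_kg`` that value is used
    directly for C_ds; otherwise the fresh-mass chain C_dp = C_fd·M_f/M_d
    applies.  A negative S_kg is returned flagged, not raised.
    """
    if throughput_kg <= 0:
        raise ValueError("throughput must be positive")
    cs = annual_cost / throughput_kg
    if scenario.dried_cost_per_kg is not None:
        cds = scenario.dried_cost_per_kg
        cdp = cds - cs
    else:
        if scenario.fresh_mass_per_batch_kg is None:
            raise ValueError("need dried_cost_per_kg or fresh_mass_per_batch_kg")
        cdp = scenario.fresh_price_per_kg * (
            scenario.fresh_mass_per_batch_kg / scenario.batch_mass_kg
        )
        cds = cdp + cs
    skg = scenario.selling_price_per_kg - cds
    return {
        "drying_cost_per_kg": cs,
        "fresh_cost_per_kg_dried": cdp,
        "dried_product_cost_per_kg": cds,
        "savings_per_kg": skg,
        "loss_making": skg < 0,
    }


def savings_cascade(
    savings_per_kg: float,
    batch_mass_kg: float,
    batch_time_min: float,
    minutes_per_day: float,
    days_per_year: float,
    year: int = 1,
) -> Dict[str, float]:
    """Savings per batch, per day, and in year j with (1+j)^(j−1) growth."""
    if year < 1 or int(year) != year:
        raise ValueError("year must be a positive integer")
    sb = savings_per_kg * batch_mass_kg
    sd = sb * (minutes_per_day / batch_time_min)
    sj = sd * days_per_year * (1.0 + year) ** (year - 1)
    return {
        "savings_per_batch": sb,
        "savings_per_day": sd,
        f"savings_year_{int(year)}": sj,
    }


def payback_period(
    capital_cost: float, savings_year_1: float, interest_rate: float, inflation_rate: float
) -> float:
    """Inflation-adjusted payback time in years.

    Ŧ = ln[1 − (C_cc/S_1)(d−i)] / ln((1+i)/(1+d)).  When d = i the
    formula degenerates and the simple ratio C_cc/S_1 is returned.
    """
    if savings_year_1 <= 0:
        raise ValueError("first-year savings must be positive to pay back")
    d, i = float(interest_rate), float(inflation_rate)
    if d == i:
        return capital_cost / savings_year_1
    arg = 1.0 - (capital_cost / savings_year_1) * (d - i)
    if arg <= 0:
        raise ValueError("savings never recover the capital cost at these rates")
    return math.log(arg) / math.log((1.0 + i) / (1.0 + d))


def evaluate_scenario(scenario: EconomicScenario) -> EconomicResult:
    """Run the full annualized-cost → savings → payback chain."""
    costs = annual_costs(scenario)
    my = annual_throughput(
        scenario.batch_mass_kg,
        scenario.batch_time_min,
        scenario.minutes_per_day,
        scenario.days_per_year,
    )
    units = unit_costs(scenario, costs["annual_cost"], my)
    cascade = savings_cascade(
        units["savings_per_kg"],
        scenario.batch_mass_kg,
        scenario.batch_time_min,
        scenario.minutes_per_day,
        scenario.days_per_year,
    )
    s1 = cascade["savings_year_1"]
    payback = months = None
    if s1 > 0:
        try:
            payback = payback_period(
                scenario.capital_cost, s1, scenario.interest_rate, scenario.inflation_rate
            )
            months = 12.0 * payback
        except ValueError:
            pass  # never pays back; leave None
    return EconomicResult(
        recovery_factor=costs["recovery_factor"],
        annual_capital_cost=costs["annual_capital_cost"],
        annual_maintenance=costs["annual_maintenance"],
        annual_salvage=costs["annual_salvage"],
        annual_cost=costs["annual_cost"],
        annual_throughput_kg=my,
        drying_cost_per_kg=units["drying_cost_per_kg"],
        dried_product_cost_per_kg=units["dried_product_cost_per_kg"],
        savings_per_kg=units["savings_per_kg"],
        savings_per_batch=cascade["savings_per_batch"],
        savings_per_day=cascade["savings_per_day"],
        savings_year_1=s1,
        payback_years=payback,
        payback_months=months,
        loss_making=bool(units["loss_making"]),
    )
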