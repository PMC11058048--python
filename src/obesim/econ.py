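"""Cost and QALY accrual with discounting.

Costs are tracked on a (payer × component) grid: payers ``public``,
``private`` and ``wpl`` (work-productivity losses), components
``intervention`` (drug spend), ``chronic``, ``events``, ``monitoring``,
``lifestyle`` (diet-and-exercise programme and gym, applied to every arm)
and ``ae``.  The societal perspective sums all three payers, with the
intervention cost counted exactly once since it is assigned to a single
payer; WPL accrues only while the cohort is below the retirement age.

Utilities follow a regression baseline (BMI, age, sex) with additive
state, event and adverse-event disutilities; utility is capped at 1, which
guarantees QALYs never exceed life-years.
"""

from __future__ import annotations

from typing import Mapping

from .deck import CostSet, UtilityModel

__all__ = [
    "discount_factor",
    "baseline_utility",
    "cycle_qaly",
    "cycle_cost_grid",
    "cycle_cost",
    "perspective_total",
]

PAYERS = ("public", "private", "wpl")
COMPONENTS = ("intervention", "chronic", "events", "monitoring", "lifestyle", "ae")


def discount_factor(rate: float, cycle: int) -> float:
    """Annual discount factor ``(1 + rate)^(−cycle)``."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return (1.0 + rate) ** (-cycle)


def baseline_utility(bmi: float, age: float, fraction_female: float, model: UtilityModel) -> float:
    """Complication-free utility from the regression, capped at 1."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    u = (model.intercept + model.coef_bmi * bmi + model.coef_age * age
         + model.coef_female * fraction_female)
    return min(u, 1.0)


def cycle_qaly(alive: float, bmi: float, age: float, fraction_female: float,
               occupancy: Mapping[str, float], model: UtilityModel,
               events: Mapping[str, float] | None = None,
               on_treatment: float = 0.0,
               ae_rates: Mapping[str, float] | None = None) -> float:
    """QALYs accrued this cycle; never counted for the dead fraction."""
    u = baseline_utility(bmi, age, fraction_female, model)
    u -= sum(occupancy.get(s, 0.0) * d for s, d in model.state_disutilities.items())
    q = alive * u
    for event, rate in (events or {}).items():
        q -= alive * rate * model.event_disutilities.get(event, 0.0)
    for event, rate in (ae_rates or {}).items():
        q -= alive * on_treatment * rate * model.ae_disutilities.get(event, 0.0)
    return q


def cycle_cost_grid(alive: float, age: float, occupancy: Mapping[str, float],
                    costs: CostSet, events: Mapping[str, float] | None = None,
                    drug_cost: float = 0.0, on_treatment: float = 0.0,
                    ae_rates: Mapping[str, float] | None = None,
                    retirement_age: float = 65.0) -> dict[tuple[str, str], float]:
    """Per-cycle costs keyed by (component, payer)."""
    grid = {(c, p): 0.0 for c in COMPONENTS for p in PAYERS}
    wpl_on = age < retirement_age
    for state, row in costs.chronic.items():
        occ = occupancy.get(state, 0.0)
        if occ <= 0:
            continue
        grid[("chronic", "public")] += alive * occ * row.get("public", 0.0)
        grid[("chronic", "private")] += alive * occ * row.get("private", 0.0)
        if wpl_on:
            grid[("chronic", "wpl")] += alive * occ * row.get("wpl", 0.0)
    for event, rate in (events or {}).items():
        row = costs.events.get(event)
        if row is None or rate <= 0:
            continue
        grid[("events", "public")] += alive * rate * row.get("public", 0.0)
        grid[("events", "private")] += alive * rate * row.get("private", 0.0)
        if wpl_on:
            grid[("events", "wpl")] += alive * rate * row.get("wpl", 0.0)
    grid[("monitoring", "public")] += alive * costs.monitoring.get("public", 0.0)
    grid[("monitoring", "private")] += alive * costs.monitoring.get("private", 0.0)
    grid[("lifestyle", "public")] += alive * costs.lifestyle.get("public", 0.0)
    grid[("lifestyle", "private")] += alive * costs.lifestyle.get("private", 0.0)
    grid[("intervention", costs.drug_payer)] += alive * drug_cost
    for event, rate in (ae_rates or {}).items():
        row = costs.ae_costs.get(event)
        if row is None:
            continue
        grid[("ae", "public")] += alive * on_treatment * rate * row.get("public", 0.0)
        grid[("ae", "private")] += alive * on_treatment * rate * row.get("private", 0.0)
    return grid


def perspective_total(grid: Mapping[tuple[str, str], float], perspective: str) -> float:
    """Total cost of a (component, payer) grid under a payer perspective."""
    if perspective == "societal":
        return sum(grid.values())
    if perspective not in PAYERS:
        raise ValueError(f"unknown perspective {perspective!r}")
    return sum(v for (c, p), v in grid.items() if p == perspective)


def cycle_cost(alive: float, age: float, occupancy: Mapping[str, float], costs: CostSet,
               events: Mapping[str, float] | None = None, perspective: str = "societal",
               drug_cost: float = 0.0, on_treatment: float = 0.0,
               ae_rates: Mapping[str, float] | None = None,
               retirement_age: float = 65.0) -> float:
    """Per-cycle cost under one perspective (societal = public + private +
    WPL, the intervention cost counted once)."""
    grid = cycle_cost_grid(alive, age, occupancy, costs, events, drug_cost,
                           on_treatment, ae_rates, retirement_age)
    return perspective_total(grid, perspective)
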