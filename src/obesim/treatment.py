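"""Translates trial efficacy into per-cycle risk-factor deltas.

The engine is mean-cohort based, so an arm's effect enters each cycle as a
cohort-mean delta per surrogate endpoint.  That mean is assembled from
weighted effect streams: early responders carry the arm's own deltas (with
a geometric maintenance decay after year 1), early non-responders revert to
the diet-and-exercise deltas under the ≥5% weight-loss stopping rule, and
any stream that ceases treatment regains its deltas along the catch-up
schedule (54% after one year, 100% after two by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .deck import (
    GLYCEMIC_SUBGROUPS,
    RISK_FACTORS,
    CatchupSchedule,
    InputDeck,
    TreatmentArm,
)

__all__ = [
    "EffectStream",
    "ArmTrajectory",
    "split_responders",
    "maintenance_scaled_delta",
    "catchup_delta",
    "bariatric_trigger",
    "apply_discontinuation",
    "arm_trajectory",
]


def maintenance_scaled_delta(delta_year1: float, ratio: float, year_on_treatment: int) -> float:
    """Delta while on treatment in a given year: ``delta_year1 · ratio^(y−1)``."""
    if year_on_treatment < 1:
        raise ValueError("year_on_treatment must be >= 1")
    return delta_year1 * ratio ** (year_on_treatment - 1)


def catchup_delta(delta_at_cessation: float, years_post: int, schedule: CatchupSchedule) -> float:
    """Residual delta ``years_post`` years after cessation (0 once the
    schedule reaches full catch-up)."""
    if years_post < 1:
        raise ValueError("years_post must be >= 1")
    return delta_at_cessation * (1.0 - schedule.return_rate(years_post))


def bariatric_trigger(bmi: float, threshold: float = 35.0) -> bool:
    """Next-line bariatric surgery eligibility (inclusive threshold)."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    return bmi >= threshold


def apply_discontinuation(on_treatment: float, rate: float) -> float:
    if not (0.0 <= on_treatment <= 1.0 and 0.0 <= rate <= 1.0):
        raise ValueError("on_treatment and rate must be in [0,1]")
    return on_treatment * (1.0 - rate)


@dataclass
class EffectStream:
    """A homogeneous sub-cohort: its weight, per-subgroup year-1 deltas,
    and whether it pays drug cost while on treatment."""

    weight: float
    deltas: dict[str, dict[str, float]]
    on_drug: bool
    discontinuation: float = 0.0


def _mix_weighted(deltas: dict[str, dict[str, float]], factor: str, mix: tuple[float, float, float]) -> float:
    return sum(w * deltas[g].get(factor, 0.0) for g, w in zip(GLYCEMIC_SUBGROUPS, mix))


def _blend(a: dict[str, dict[str, float]], b: dict[str, dict[str, float]], wa: float) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for g in GLYCEMIC_SUBGROUPS:
        keys = set(a[g]) | set(b[g])
        out[g] = {k: wa * a[g].get(k, 0.0) + (1.0 - wa) * b[g].get(k, 0.0) for k in keys}
    return out


def split_responders(arm: TreatmentArm, stopping_rule: bool = True) -> list[EffectStream]:
    """Split an arm into weighted effect streams.

    With the stopping rule active, responders (weight ``responder_fraction``)
    carry the arm deltas and drug cost; non-responders carry the D&E deltas
    and only the pre-stopping-rule drug exposure.  Without the stopping rule
    the whole cohort stays on drug with the population-weighted deltas.
    """
    rf = arm.responder_fraction
    if not stopping_rule:
        return [EffectStream(1.0, _blend(arm.deltas_year1, arm.nonresponder_deltas, rf), True,
                             arm.per_cycle_discontinuation)]
    streams = []
    if rf > 0:
        streams.append(EffectStream(rf, arm.deltas_year1, True, arm.per_cycle_discontinuation))
    if rf < 1:
        streams.append(EffectStream(1.0 - rf, arm.nonresponder_deltas, False, 0.0))
    return streams


@dataclass
class ArmTrajectory:
    """Pre-computed cohort-mean effect path for one arm.

    Arrays are indexed by cycle (0..horizon; index 0 is baseline).
    ``delta[f][t]`` is the cohort-mean change in factor ``f`` during cycle
    ``t``; ``on_treatment[t]`` the on-drug proportion; ``drug_cost[t]`` the
    per-alive drug spend.  ``reversal_cycle1`` is the proportion of the
    prediabetes pool reverting to NGT at the end of cycle 1, and
    ``reversal_return_cycle`` the cycle at which ``prediabetes_return_rate``
    of the reversed pool moves back.
    """

    horizon: int
    delta: dict[str, list[float]]
    on_treatment: list[float]
    drug_cost: list[float]
    reversal_cycle1: float
    reversal_return_cycle: int
    drift_start_cycle: int

    def years_since_cessation(self, cycle: int, duration: int) -> int | None:
        return cycle - duration if cycle > duration else None


def _stream_delta_path(d1: float, ratio: float, duration: int, disc: float,
                       schedule: CatchupSchedule, horizon: int) -> list[float]:
    """Mean delta per cycle for one stream, mixing over cessation cohorts.

    A sub-cohort discontinuing at the end of cycle s keeps
    ``delta(s)·(1 − return(t−s))`` during later cycles t; the remainder
    stops at the treatment-duration boundary.
    """
    path = [0.0] * (horizon + 1)
    # mass still on treatment at the end of cycle t, and cessation masses
    on_mass = [1.0] + [0.0] * horizon
    ceased: list[tuple[int, float, float]] = []  # (cessation cycle, mass, delta at cessation)
    for t in range(1, horizon + 1):
        if t <= duration:
            prev = (1.0 - disc) ** (t - 1)
            now = prev * (1.0 - disc)
            on_mass[t] = now
            if prev - now > 0:
                ceased.append((t, prev - now, maintenance_scaled_delta(d1, ratio, t)))
            if t == duration and now > 0:
                ceased.append((t, now, maintenance_scaled_delta(d1, ratio, t)))
        else:
            on_mass[t] = 0.0
    for t in range(1, horizon + 1):
        val = 0.0
        if t <= duration:
            val += on_mass[t] * maintenance_scaled_delta(d1, ratio, t)
        for s, mass, d_at in ceased:
            if t > s:
                val += mass * catchup_delta(d_at, t - s, schedule)
        path[t] = val
    return path


def arm_trajectory(arm: TreatmentArm, deck: InputDeck) -> ArmTrajectory:
    """Assemble the cohort-mean effect path for ``arm`` under the deck's
    scenario toggles (stopping rule, estimand, discontinuation)."""
    horizon = deck.settings.horizon_years
    schedule = deck.catchup
    mix0 = deck.cohort.glycemic_mix
    toggles = deck.toggles
    duration = arm.treatment_duration

    streams = split_responders(arm, stopping_rule=toggles.stopping_rule)
    # Treatment-policy effects are population-level already: per-cycle
    # discontinuation then neither erodes efficacy nor drug exposure.
    apply_disc = toggles.discontinuation and toggles.estimand == "trial_product"

    delta: dict[str, list[float]] = {f: [0.0] * (horizon + 1) for f in RISK_FACTORS}
    on_treatment = [0.0] * (horizon + 1)
    drug_cost = [0.0] * (horizon + 1)
    reversal = 0.0
    for stream in streams:
        disc = stream.discontinuation if apply_disc else 0.0
        for f in RISK_FACTORS:
            d1 = _mix_weighted(stream.deltas, f, mix0)
            if d1 != 0.0:
                p = _stream_delta_path(d1, arm.maintenance_ratio, duration, disc, schedule, horizon)
                for t in range(horizon + 1):
                    delta[f][t] += stream.weight * p[t]
        # prediabetes reversal is defined on the prediabetes pool directly
        reversal += stream.weight * stream.deltas["prediabetes"].get("prediabetes_reversal", 0.0)
        if stream.on_drug:
            for t in range(1, min(duration, horizon) + 1):
                frac = stream.weight * (1.0 - disc) ** t
                on_treatment[t] += frac
                drug_cost[t] += frac * arm.annual_drug_cost
        elif arm.nonresponder_cost_years > 0:
            # pre-stopping-rule exposure: part of cycle 1 on therapeutic dose
            drug_cost[1] += stream.weight * arm.nonresponder_cost_years * arm.annual_drug_cost

    full_catchup_years = len(schedule.return_rates)
    return ArmTrajectory(
        horizon=horizon,
        delta=delta,
        on_treatment=on_treatment,
        drug_cost=drug_cost,
        reversal_cycle1=reversal,
        reversal_return_cycle=duration + 1,
        drift_start_cycle=duration + full_catchup_years,
    )
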