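"""Annual-cycle closed-cohort Markov engine.

The cohort is advanced one year at a time with a fixed within-cycle order:
(1) treatment status (stopping rule, discontinuation, catch-up progress),
(2) risk-factor update from the arm's effect trajectory, (3) complication
incidence from the updated factors, (4) mortality, (5) cost/QALY accrual on
end-of-cycle occupancy.  Disease states are quasi-independent prevalence
flags on the mean cohort; T2D and the cancers are absorbing, acute events
(MI, UA, stroke, TIA, knee surgery) are per-cycle rates feeding one-off
costs/disutilities and the post-event chronic states.

Alongside the treated risk-factor path the engine carries an untreated
reference path (zero treatment deltas); scenario switches that remove the
weight-loss effect on a complication make its equation read the reference
path, which is identical across arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import pandas as pd

from . import econ, risk, treatment
from .deck import ConfigurationError, InputDeck, TreatmentArm
from .treatment import ArmTrajectory

__all__ = ["CohortState", "SimulationResult", "glycemic_transition", "advance_cycle", "run_simulation"]


def glycemic_transition(mix, t2d_incidence: float = 0.0, reversal: float = 0.0,
                        return_rate: float = 0.0, reversed_pool: float = 0.0,
                        t2d_incidence_prediabetes: float | None = None):
    """One glycemic-status step; returns the new (NGT, prediabetes, T2D) mix.

    T2D incidence drains both the NGT and prediabetes pools (T2D is
    absorbing); ``reversal`` moves prediabetes → NGT; ``return_rate`` moves
    ``return_rate·reversed_pool`` of previously reverted mass NGT →
    prediabetes (capped at the NGT pool).
    """
    probs = [t2d_incidence, reversal, return_rate]
    if t2d_incidence_prediabetes is not None:
        probs.append(t2d_incidence_prediabetes)
    if any(p < 0 or p > 1 for p in probs):
        raise ValueError("probabilities must be in [0,1]")
    ngt, pre, t2d = mix
    inc_ngt = t2d_incidence
    inc_pre = t2d_incidence if t2d_incidence_prediabetes is None else t2d_incidence_prediabetes
    new_t2d = t2d + ngt * inc_ngt + pre * inc_pre
    ngt *= 1.0 - inc_ngt
    pre *= 1.0 - inc_pre
    moved = pre * reversal
    ngt += moved
    pre -= moved
    back = min(return_rate * reversed_pool, ngt)
    ngt -= back
    pre += back
    return (ngt, pre, new_t2d)


@dataclass
class CohortState:
    """Per-cycle description of the mean cohort."""

    cycle: int = 0
    age: float = 50.0
    alive: float = 1.0
    risk_factors: dict[str, float] = field(default_factory=dict)
    glycemic_mix: tuple[float, float, float] = (0.26, 0.464, 0.276)
    state_occupancy: dict[str, float] = field(default_factory=dict)
    on_treatment: float = 0.0
    years_since_cessation: int | None = None
    reversed_pool: float = 0.0
    reference_factors: dict[str, float] = field(default_factory=dict)
    reference_mix: tuple[float, float, float] = (0.26, 0.464, 0.276)
    bariatric_offset: float = 0.0
    bariatric_done: bool = False
    events: dict[str, float] = field(default_factory=dict)

    @property
    def occupancy_with_t2d(self) -> dict[str, float]:
        occ = dict(self.state_occupancy)
        occ["t2d"] = self.glycemic_mix[2]
        return occ


def _initial_state(deck: InputDeck) -> CohortState:
    c = deck.cohort
    factors = {"bmi": c.bmi, "sbp": c.sbp, "tc": c.total_cholesterol,
               "hdl": c.hdl_cholesterol, "hba1c": c.hba1c_t2d}
    state = CohortState(
        cycle=0, age=c.start_age, alive=1.0,
        risk_factors=dict(factors), glycemic_mix=tuple(c.glycemic_mix),
        reference_factors=dict(factors), reference_mix=tuple(c.glycemic_mix),
    )
    state.state_occupancy = {s: 0.0 for s in ("sleep_apnea", "post_acs", "post_stroke",
                                              "colon_cancer", "breast_cancer",
                                              "endometrial_cancer", "post_knee_surgery")}
    if "sleep_apnea" in deck.risk.equations:
        state.state_occupancy["sleep_apnea"] = risk.annual_risk(
            "sleep_apnea", _profile(deck, factors, state.glycemic_mix), deck.risk)
    return state


def _profile(deck: InputDeck, factors: dict[str, float], mix, age: float | None = None,
             prediabetes: float | None = None) -> dict[str, float]:
    c = deck.cohort
    return risk.build_covariates(
        age=c.start_age if age is None else age,
        fraction_female=c.fraction_female,
        bmi=factors["bmi"], sbp=factors["sbp"], tc=factors["tc"], hdl=factors["hdl"],
        hba1c=factors["hba1c"], smoker=c.smoker_fraction,
        prediabetes=mix[1] if prediabetes is None else prediabetes,
        diabetes=mix[2],
    )


def _factors_at(deck: InputDeck, traj: ArmTrajectory, cycle: int, bariatric_offset: float) -> tuple[dict, dict]:
    """(treated, reference) risk-factor means for a cycle."""
    c = deck.cohort
    drift = deck.catchup.natural_bmi_drift * max(0, cycle - traj.drift_start_cycle)
    base = {"bmi": c.bmi + drift, "sbp": c.sbp, "tc": c.total_cholesterol,
            "hdl": c.hdl_cholesterol,
            "hba1c": c.hba1c_t2d + deck.risk.hba1c_annual_increase * cycle}
    treated = {
        "bmi": max(base["bmi"] + traj.delta["bmi"][cycle] + bariatric_offset, 10.0),
        "sbp": base["sbp"] + traj.delta["sbp"][cycle],
        "tc": base["tc"] + traj.delta["tc"][cycle],
        "hdl": base["hdl"] + traj.delta["hdl"][cycle],
        "hba1c": base["hba1c"] + traj.delta["hba1c"][cycle],
    }
    return treated, base


def advance_cycle(state: CohortState, arm: TreatmentArm, deck: InputDeck,
                  trajectory: ArmTrajectory | None = None) -> CohortState:
    """Advance the cohort by one annual cycle (pure; returns a new state)."""
    traj = trajectory if trajectory is not None else treatment.arm_trajectory(arm, deck)
    t = state.cycle + 1
    if state.alive <= 0.0:
        return replace(state, cycle=t, age=state.age + 1.0, events={})
    c = deck.cohort
    toggles = deck.toggles
    age = state.age + 1.0

    # (1) treatment status
    on_treatment = traj.on_treatment[t] if t <= traj.horizon else 0.0
    years_since = traj.years_since_cessation(t, arm.treatment_duration)

    # (2) risk factors (treated + untreated reference paths)
    bariatric_offset = state.bariatric_offset
    bariatric_done = state.bariatric_done
    events: dict[str, float] = {}
    treated, reference = _factors_at(deck, traj, min(t, traj.horizon), bariatric_offset)
    if (toggles.bariatric_next_line and not bariatric_done and on_treatment == 0.0
            and years_since is not None
            and treatment.bariatric_trigger(treated["bmi"], deck.bariatric.bmi_threshold)):
        events["bariatric_surgery"] = deck.bariatric.uptake
        bariatric_offset += deck.bariatric.uptake * deck.bariatric.bmi_delta
        bariatric_done = True
        treated, reference = _factors_at(deck, traj, min(t, traj.horizon), bariatric_offset)

    # (3) incidences from updated risk factors
    eqs = deck.risk.equations
    occ = dict(state.state_occupancy)

    # glycemic transitions: T2D incidence always reads the treated path
    inc_ngt = risk.annual_risk("t2d", _profile(deck, treated, state.glycemic_mix, age, prediabetes=0.0), deck.risk) if "t2d" in eqs else 0.0
    inc_pre = risk.annual_risk("t2d", _profile(deck, treated, state.glycemic_mix, age, prediabetes=1.0), deck.risk) if "t2d" in eqs else 0.0
    reversal = traj.reversal_cycle1 if t == 1 else 0.0
    return_rate = deck.catchup.prediabetes_return_rate if t == traj.reversal_return_cycle else 0.0
    pre_pool_before = state.glycemic_mix[1]
    mix = glycemic_transition(state.glycemic_mix, inc_ngt, reversal, return_rate,
                              state.reversed_pool, t2d_incidence_prediabetes=inc_pre)
    reversed_pool = state.reversed_pool + pre_pool_before * (1.0 - inc_pre) * reversal
    if return_rate > 0.0:
        reversed_pool *= 1.0 - return_rate
    t2d_inflow = mix[2] - state.glycemic_mix[2]

    ref_inc_ngt = risk.annual_risk("t2d", _profile(deck, reference, state.reference_mix, age, prediabetes=0.0), deck.risk) if "t2d" in eqs else 0.0
    ref_inc_pre = risk.annual_risk("t2d", _profile(deck, reference, state.reference_mix, age, prediabetes=1.0), deck.risk) if "t2d" in eqs else 0.0
    ref_mix = glycemic_transition(state.reference_mix, ref_inc_ngt, 0.0, 0.0,
                                  t2d_incidence_prediabetes=ref_inc_pre)

    # sleep apnea: a BMI-driven prevalence, always responsive to weight loss
    if "sleep_apnea" in eqs:
        occ["sleep_apnea"] = risk.annual_risk("sleep_apnea", _profile(deck, treated, mix, age), deck.risk)

    # cardiovascular disease
    cvd_factors, cvd_mix = (treated, mix) if toggles.effect_on_cvd else (reference, ref_mix)
    if "cvd_primary" in eqs:
        at_risk = max(1.0 - occ["post_acs"] - occ["post_stroke"], 0.0)
        q_prim = risk.annual_risk("cvd_primary", _profile(deck, cvd_factors, cvd_mix, age), deck.risk)
        q_rec = (risk.annual_risk("cvd_recurrent", _profile(deck, cvd_factors, cvd_mix, age), deck.risk)
                 if "cvd_recurrent" in eqs else 0.0)
        total_rate = q_prim * at_risk + q_rec * (occ["post_acs"] + occ["post_stroke"])
        for ev, split in deck.risk.cvd_event_split.items():
            events[ev] = events.get(ev, 0.0) + total_rate * split
        occ["post_acs"] = min(occ["post_acs"] + events.get("mi", 0.0) + events.get("ua", 0.0), 1.0)
        occ["post_stroke"] = min(occ["post_stroke"] + events.get("stroke", 0.0), 1.0)

    # cancers (absorbing); breast/endometrial restricted to post-menopausal women
    cancer_factors = treated if toggles.effect_on_cancer else reference
    post_menopausal = 1.0 if age >= deck.risk.menopause_age else 0.0
    for eq_name, state_name, eligible in (
        ("colon_cancer", "colon_cancer", 1.0),
        ("breast_cancer", "breast_cancer", c.fraction_female * post_menopausal),
        ("endometrial_cancer", "endometrial_cancer", c.fraction_female * post_menopausal),
    ):
        if eq_name in eqs and eligible > 0:
            q = risk.annual_risk(eq_name, _profile(deck, cancer_factors, mix, age), deck.risk)
            inflow = q * max(eligible - occ[state_name], 0.0)
            events[eq_name] = inflow
            occ[state_name] = min(occ[state_name] + inflow, 1.0)

    # knee osteoarthritis surgery (one-off event into a post-surgery state)
    knee_factors = treated if toggles.effect_on_knee else reference
    if "knee_surgery" in eqs:
        q = risk.annual_risk("knee_surgery", _profile(deck, knee_factors, mix, age), deck.risk)
        rate = q * max(1.0 - occ["post_knee_surgery"], 0.0)
        events["knee_surgery"] = rate
        occ["post_knee_surgery"] = min(occ["post_knee_surgery"] + rate, 1.0)

    # (4) mortality
    bmi_for_hr = treated["bmi"] if toggles.effect_on_mortality else reference["bmi"]
    occ_mort = dict(occ)
    occ_mort["t2d"] = mix[2]
    fatal_events = {e: r for e, r in events.items()
                    if e in ("mi", "ua", "stroke", "knee_surgery", "bariatric_surgery")}
    q_death = risk.all_cause_mortality(age, c.fraction_female, bmi_for_hr, occ_mort,
                                       deck.mortality, fatal_events)
    alive = state.alive * (1.0 - q_death)
    events["deaths"] = state.alive * q_death

    return CohortState(
        cycle=t, age=age, alive=alive,
        risk_factors=treated, glycemic_mix=mix, state_occupancy=occ,
        on_treatment=on_treatment, years_since_cessation=years_since,
        reversed_pool=reversed_pool, reference_factors=reference, reference_mix=ref_mix,
        bariatric_offset=bariatric_offset, bariatric_done=bariatric_done,
        events=events,
    )


@dataclass
class SimulationResult:
    """Discounted/undiscounted LYs, QALYs and (payer × component) costs,
    cumulative incidence per complication, and the per-cycle trace."""

    arm: str
    trace: list[CohortState]
    ly: dict[str, float]
    qaly: dict[str, float]
    cost_grid: dict[str, dict[tuple[str, str], float]]
    cumulative_incidence: dict[str, float]
    cumulative_deaths: float
    bmi_trajectory: list[float]
    per_cycle: list[dict[str, Any]]

    def total_cost(self, perspective: str = "societal", discounted: bool = True) -> float:
        return econ.perspective_total(self.cost_grid["discounted" if discounted else "undiscounted"], perspective)

    def intervention_cost(self, perspective: str = "societal", discounted: bool = True) -> float:
        grid = self.cost_grid["discounted" if discounted else "undiscounted"]
        if perspective == "societal":
            return sum(v for (comp, _p), v in grid.items() if comp == "intervention")
        return sum(v for (comp, p), v in grid.items() if comp == "intervention" and p == perspective)

    def disease_cost(self, perspective: str = "societal", discounted: bool = True) -> float:
        return self.total_cost(perspective, discounted) - self.intervention_cost(perspective, discounted)

    def totals(self, perspective: str = "societal") -> dict[str, float]:
        return {
            "ly": self.ly["discounted"],
            "qaly": self.qaly["discounted"],
            "total_cost": self.total_cost(perspective),
            "intervention_cost": self.intervention_cost(perspective),
            "disease_cost": self.disease_cost(perspective),
        }

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_cycle)


def run_simulation(deck: InputDeck, arm_name: str,
                   initial_state: CohortState | None = None) -> SimulationResult:
    """Run the cohort model for one arm over the deck's horizon.

    The trace has ``horizon_years + 1`` entries (cycle 0 = baseline) and
    the totals are exactly the sum of the per-cycle accruals; the run is
    deterministic given the deck.
    """
    deck.validate()
    arm = deck.arm(arm_name)
    settings = deck.settings
    traj = treatment.arm_trajectory(arm, deck)
    state = initial_state if initial_state is not None else _initial_state(deck)
    trace = [state]
    per_cycle: list[dict[str, Any]] = []
    ly = {"discounted": 0.0, "undiscounted": 0.0}
    qaly = {"discounted": 0.0, "undiscounted": 0.0}
    grid_d: dict[tuple[str, str], float] = {}
    grid_u: dict[tuple[str, str], float] = {}
    cum_inc: dict[str, float] = {}
    cum_deaths = 0.0
    bmi_path = [state.risk_factors["bmi"]]

    for t in range(state.cycle + 1, settings.horizon_years + 1):
        prev_alive = state.alive
        state = advance_cycle(state, arm, deck, traj)
        trace.append(state)
        bmi_path.append(state.risk_factors["bmi"])
        alive_eff = 0.5 * (prev_alive + state.alive) if settings.half_cycle_correction else state.alive

        df_b = econ.discount_factor(settings.discount_rate_benefits, t)
        df_c = econ.discount_factor(settings.discount_rate_costs, t)
        ly["undiscounted"] += alive_eff
        ly["discounted"] += alive_eff * df_b

        occ = state.occupancy_with_t2d
        event_rates = {e: r for e, r in state.events.items() if e != "deaths"}
        q = econ.cycle_qaly(alive_eff, state.risk_factors["bmi"], state.age,
                            deck.cohort.fraction_female, occ, deck.utilities,
                            events=event_rates, on_treatment=state.on_treatment,
                            ae_rates=arm.ae_rates)
        qaly["undiscounted"] += q
        qaly["discounted"] += q * df_b

        drug = traj.drug_cost[t] if t <= traj.horizon else 0.0
        grid = econ.cycle_cost_grid(alive_eff, state.age, occ, deck.costs,
                                    events=event_rates, drug_cost=drug,
                                    on_treatment=state.on_treatment, ae_rates=arm.ae_rates,
                                    retirement_age=settings.retirement_age)
        cost_total = 0.0
        for key, v in grid.items():
            grid_u[key] = grid_u.get(key, 0.0) + v
            grid_d[key] = grid_d.get(key, 0.0) + v * df_c
            cost_total += v

        for ev, rate in state.events.items():
            if ev == "deaths":
                continue
            cum_inc[ev] = cum_inc.get(ev, 0.0) + rate * prev_alive
        cum_inc["t2d"] = cum_inc.get("t2d", 0.0) + max(
            state.glycemic_mix[2] - trace[-2].glycemic_mix[2], 0.0) * prev_alive
        cum_deaths += state.events.get("deaths", 0.0)

        per_cycle.append({
            "cycle": t, "age": state.age, "alive": state.alive,
            "bmi": state.risk_factors["bmi"],
            "ngt": state.glycemic_mix[0], "prediabetes": state.glycemic_mix[1],
            "t2d": state.glycemic_mix[2],
            "on_treatment": state.on_treatment,
            "ly": alive_eff, "qaly": q, "cost_societal": cost_total,
            "deaths": state.events.get("deaths", 0.0),
        })

    return SimulationResult(
        arm=arm_name, trace=trace, ly=ly, qaly=qaly,
        cost_grid={"discounted": grid_d, "undiscounted": grid_u},
        cumulative_incidence=cum_inc, cumulative_deaths=cum_deaths,
        bmi_trajectory=bmi_path, per_cycle=per_cycle,
    )
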