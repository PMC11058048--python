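import math

import pytest

from obesim.core import CohortState, advance_cycle, glycemic_transition, run_simulation
from obesim.deck import ConfigurationError, DeckValidationError, RiskEquation

from conftest import make_inert_deck, zero_all_effects


# ---------------------------------------------------------------------------
# glycemic transitions
# ---------------------------------------------------------------------------

def test_glycemic_transition_identity():
    mix = (0.26, 0.464, 0.276)
    assert glycemic_transition(mix) == pytest.approx(mix)


def test_glycemic_full_reversal_empties_prediabetes():
    out = glycemic_transition((0.26, 0.464, 0.276), reversal=1.0)
    assert out == pytest.approx((0.724, 0.0, 0.276))


def test_glycemic_t2d_incidence_drains_both_pools():
    out = glycemic_transition((0.3, 0.4, 0.3), t2d_incidence=0.05)
    assert out == pytest.approx((0.285, 0.38, 0.335))
    assert sum(out) == pytest.approx(1.0)


def test_glycemic_post_cessation_return_mass_balance():
    """12.7% of a reversed pool of 0.2 moves NGT → prediabetes."""
    mix = (0.6, 0.2, 0.2)
    out = glycemic_transition(mix, return_rate=0.127, reversed_pool=0.2)
    moved = 0.127 * 0.2
    assert out == pytest.approx((0.6 - moved, 0.2 + moved, 0.2))
    assert moved == pytest.approx(0.0254)


def test_glycemic_rejects_negative_probability():
    with pytest.raises(ValueError):
        glycemic_transition((0.3, 0.4, 0.3), t2d_incidence=-0.1)


def test_t2d_is_absorbing():
    out = glycemic_transition((0.0, 0.0, 1.0), t2d_incidence=0.5, reversal=1.0,
                              return_rate=1.0, reversed_pool=0.5)
    assert out[2] == 1.0


# ---------------------------------------------------------------------------
# advance_cycle
# ---------------------------------------------------------------------------

def test_inert_cycle_changes_only_clock(deck):
    deck = make_inert_deck(deck)
    deck.validate()
    state = CohortState(cycle=0, age=50.0, alive=1.0,
                        risk_factors={"bmi": 37.5, "sbp": 133.0, "tc": 4.9, "hdl": 1.25, "hba1c": 8.1},
                        reference_factors={"bmi": 37.5, "sbp": 133.0, "tc": 4.9, "hdl": 1.25, "hba1c": 8.1})
    deck.risk.hba1c_annual_increase = 0.0
    new = advance_cycle(state, deck.arms["diet_exercise"], deck)
    assert new.cycle == 1 and new.age == 51.0
    assert new.alive == 1.0
    assert new.risk_factors == pytest.approx(state.risk_factors)
    assert new.glycemic_mix == pytest.approx(state.glycemic_mix)


def test_mortality_probability_applied_directly(deck):
    deck = make_inert_deck(deck)
    for age in deck.mortality.life_table:
        deck.mortality.life_table[age] = {"female": 0.01, "male": 0.01}
    state = CohortState(age=50.0, alive=1.0,
                        risk_factors={"bmi": 25.0, "sbp": 120, "tc": 4, "hdl": 1, "hba1c": 5},
                        reference_factors={"bmi": 25.0, "sbp": 120, "tc": 4, "hdl": 1, "hba1c": 5})
    new = advance_cycle(state, deck.arms["diet_exercise"], deck)
    assert new.alive == pytest.approx(0.99)


def test_dead_cohort_only_ages(deck):
    state = CohortState(cycle=3, age=53.0, alive=0.0)
    new = advance_cycle(state, deck.arms["diet_exercise"], deck)
    assert (new.cycle, new.age, new.alive) == (4, 54.0, 0.0)


# ---------------------------------------------------------------------------
# run_simulation
# ---------------------------------------------------------------------------

def test_unknown_arm_raises_configuration_error(deck):
    with pytest.raises(ConfigurationError, match="unknown arm"):
        run_simulation(deck, "ozempic")


def test_invalid_deck_lists_violations(deck):
    deck.cohort.glycemic_mix = (0.5, 0.5, 0.5)
    with pytest.raises(DeckValidationError, match="glycemic_mix"):
        run_simulation(deck, "semaglutide")


def test_trace_has_horizon_plus_one_entries(deck):
    deck.settings.horizon_years = 7
    res = run_simulation(deck, "semaglutide")
    assert len(res.trace) == 8
    assert res.trace[0].cycle == 0


def test_single_cycle_discounting_closed_form(deck):
    """Horizon 1, no incidence, no mortality: LY = 1 undiscounted and
    1/1.015 discounted at 1.5%."""
    deck = make_inert_deck(deck)
    deck.settings.horizon_years = 1
    res = run_simulation(deck, "diet_exercise")
    assert res.ly["undiscounted"] == pytest.approx(1.0)
    assert res.ly["discounted"] == pytest.approx(1 / 1.015)


def test_null_treatment_arm_reproduces_reference_exactly(deck):
    """An arm with zero deltas, zero drug cost and zero AEs is
    indistinguishable from standard of care, total for total."""
    deck = zero_all_effects(deck, ["semaglutide", "diet_exercise"])
    arm = deck.arms["semaglutide"]
    arm.annual_drug_cost = 0.0
    arm.ae_rates = {}
    deck.arms["diet_exercise"].ae_rates = {}
    a = run_simulation(deck, "semaglutide")
    b = run_simulation(deck, "diet_exercise")
    assert a.ly == b.ly
    assert a.qaly == b.qaly
    assert a.cost_grid["discounted"] == b.cost_grid["discounted"]
    assert a.cost_grid["undiscounted"] == b.cost_grid["undiscounted"]


def test_zero_discount_identity(deck):
    deck.settings.discount_rate_costs = 0.0
    deck.settings.discount_rate_benefits = 0.0
    res = run_simulation(deck, "semaglutide")
    assert res.ly["discounted"] == res.ly["undiscounted"]
    assert res.qaly["discounted"] == res.qaly["undiscounted"]
    assert res.total_cost(discounted=True) == pytest.approx(res.total_cost(discounted=False))


def test_discounted_totals_below_undiscounted(deck):
    res = run_simulation(deck, "semaglutide")
    assert res.ly["discounted"] < res.ly["undiscounted"]
    assert res.total_cost(discounted=True) < res.total_cost(discounted=False)


def test_horizon_additivity_of_undiscounted_totals(deck):
    """A 0→40 run equals a 0→15 run chained with a 15→40 run re-seeded
    from the cycle-15 state (undiscounted accruals)."""
    deck.settings.discount_rate_costs = 0.0
    deck.settings.discount_rate_benefits = 0.0
    full = run_simulation(deck, "semaglutide")
    first = run_simulation(deck, "semaglutide")
    mid_state = first.trace[15]
    second = run_simulation(deck, "semaglutide", initial_state=mid_state)
    ly_first = sum(r["ly"] for r in first.per_cycle[:15])
    assert ly_first + second.ly["undiscounted"] == pytest.approx(full.ly["undiscounted"], rel=1e-12)
    q_first = sum(r["qaly"] for r in first.per_cycle[:15])
    assert q_first + second.qaly["undiscounted"] == pytest.approx(full.qaly["undiscounted"], rel=1e-12)


def test_alive_fraction_monotone_and_mix_conserved(deck):
    res = run_simulation(deck, "semaglutide")
    alive = [s.alive for s in res.trace]
    assert all(b <= a for a, b in zip(alive, alive[1:]))
    for s in res.trace:
        assert sum(s.glycemic_mix) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= occ <= 1.0 for occ in s.state_occupancy.values())


def test_increasing_mortality_decreases_life_years(deck):
    base = run_simulation(deck, "diet_exercise").ly["discounted"]
    worse = deck.copy()
    for age in worse.mortality.life_table:
        row = worse.mortality.life_table[age]
        worse.mortality.life_table[age] = {s: min(q * 1.5, 1.0) for s, q in row.items()}
    worse.mortality.hr_bmi_per_unit += 0.01
    worse.mortality.case_fatalities = {e: min(cf * 1.5, 1.0) for e, cf in worse.mortality.case_fatalities.items()}
    assert run_simulation(worse, "diet_exercise").ly["discounted"] < base


def test_qaly_never_exceeds_life_years(deck):
    for arm in deck.arms:
        res = run_simulation(deck, arm)
        assert res.qaly["discounted"] <= res.ly["discounted"]
        assert res.qaly["undiscounted"] <= res.ly["undiscounted"]


def test_weight_loss_weakly_raises_life_years(deck):
    """Lowering cohort BMI (all else equal) cannot reduce survival: the
    semaglutide arm, with the deepest BMI reduction, attains at least the
    reference arm's life-years."""
    ly_ref = run_simulation(deck, "diet_exercise").ly["discounted"]
    ly_sema = run_simulation(deck, "semaglutide").ly["discounted"]
    assert ly_sema >= ly_ref


def test_three_cycle_cumulative_incidence_matches_enumeration(deck):
    """With hand-specified constant rates the engine's cumulative T2D and
    colon-cancer incidence must match a spreadsheet-style enumeration."""
    deck = make_inert_deck(deck)
    deck.settings.horizon_years = 3
    q_t2d, q_colon, q_die = 0.05, 0.01, 0.02
    deck.risk.equations = {
        "t2d": RiskEquation("t2d", "hazard", -math.log(1 - q_t2d), {}),
        "colon_cancer": RiskEquation("colon_cancer", "hazard", -math.log(1 - q_colon), {}),
    }
    for age in deck.mortality.life_table:
        deck.mortality.life_table[age] = {"female": q_die, "male": q_die}
    res = run_simulation(deck, "diet_exercise")

    # independent enumeration
    ngt, pre, t2d = deck.cohort.glycemic_mix
    alive, colon, cum_t2d, cum_colon = 1.0, 0.0, 0.0, 0.0
    for _ in range(3):
        new_t2d = (ngt + pre) * q_t2d
        ngt, pre, t2d = ngt * (1 - q_t2d), pre * (1 - q_t2d), t2d + new_t2d
        inflow = q_colon * (1.0 - colon)
        cum_t2d += new_t2d * alive
        cum_colon += inflow * alive
        colon += inflow
        alive *= 1 - q_die
    assert res.cumulative_incidence["t2d"] == pytest.approx(cum_t2d, abs=1e-12)
    assert res.cumulative_incidence["colon_cancer"] == pytest.approx(cum_colon, abs=1e-12)
    assert res.trace[-1].alive == pytest.approx((1 - q_die) ** 3, abs=1e-12)


def test_scenario4_switches_equalize_streams(deck):
    """Removing the weight-loss effect on cancer/CVD/mortality/knee leaves
    T2D incidence treatment-responsive but equalizes the other streams."""
    deck.mortality.post_state_hrs["t2d"] = 1.0  # isolate the switched-off pathways
    base_t2d = {a: [s.glycemic_mix[2] for s in run_simulation(deck, a).trace]
                for a in ("diet_exercise", "semaglutide")}
    deck.toggles.effect_on_cancer = False
    deck.toggles.effect_on_cvd = False
    deck.toggles.effect_on_mortality = False
    deck.toggles.effect_on_knee = False
    res = {a: run_simulation(deck, a) for a in ("diet_exercise", "semaglutide")}
    for arm, r in res.items():
        assert [s.glycemic_mix[2] for s in r.trace] == pytest.approx(base_t2d[arm], rel=1e-9)
    a, b = res["diet_exercise"], res["semaglutide"]
    for stream in ("mi", "stroke", "colon_cancer", "knee_surgery"):
        assert b.cumulative_incidence[stream] == pytest.approx(a.cumulative_incidence[stream], rel=1e-9)
    # T2D still responds to weight loss
    assert b.cumulative_incidence["t2d"] < a.cumulative_incidence["t2d"]


def test_half_cycle_correction_averages_cycle_boundaries(deck):
    res = run_simulation(deck, "diet_exercise")
    deck.settings.half_cycle_correction = True
    hc = run_simulation(deck, "diet_exercise")
    assert hc.ly["undiscounted"] > res.ly["undiscounted"]  # averages in the larger start-of-cycle cohort
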