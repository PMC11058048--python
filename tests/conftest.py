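import pytest
from hypothesis import settings as hypothesis_settings

from obesim import default_deck
from obesim.deck import GLYCEMIC_SUBGROUPS, InputDeck

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")


@pytest.fixture(scope="session")
def base_deck() -> InputDeck:
    return default_deck(seed=0)


@pytest.fixture()
def deck(base_deck) -> InputDeck:
    """A fresh mutable copy of the default deck."""
    return base_deck.copy()


def zero_all_effects(deck: InputDeck, arm_names=None) -> InputDeck:
    """Zero every treatment delta (and reversal) for the given arms."""
    for name, arm in deck.arms.items():
        if arm_names is not None and name not in arm_names:
            continue
        for table in (arm.deltas_year1, arm.nonresponder_deltas):
            for g in GLYCEMIC_SUBGROUPS:
                for k in table[g]:
                    table[g][k] = 0.0
    return deck


def make_inert_deck(deck: InputDeck) -> InputDeck:
    """A deck with no incidence, no mortality and no treatment effects:
    the cohort just ages."""
    deck = zero_all_effects(deck)
    deck.risk.equations = {}
    for age in deck.mortality.life_table:
        deck.mortality.life_table[age] = {"female": 0.0, "male": 0.0}
    deck.mortality.case_fatalities = {}
    deck.mortality.post_state_hrs = {}
    deck.mortality.cause_deduction = 0.0
    deck.mortality.hr_bmi_per_unit = 1.0
    deck.catchup.natural_bmi_drift = 0.0
    for arm in deck.arms.values():
        arm.annual_drug_cost = 0.0
        arm.ae_rates = {}
    return deck
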