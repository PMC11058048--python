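"""Risk equations and mortality.

Annual complication risks come from declared-form equations (logistic or
exponential-hazard linear predictors on centred risk factors).  All-cause
mortality is decomposed: a cause-deleted life-table background, scaled by a
per-BMI-unit hazard ratio and post-state hazard ratios, combined with the
case fatality of the acute events occurring in the cycle.

Covariate vocabulary (what a profile dict may supply): ``age_c`` (age − 50),
``female`` (fraction female), ``bmi_c`` (BMI − 25), ``sbp_c`` (SBP − 120),
``tchdl_c`` (TC/HDL ratio − 4), ``hba1c_c`` (HbA1c − 5.5), ``smoker``,
``prediabetes`` and ``diabetes`` (pool indicators / cohort shares).
"""

from __future__ import annotations

import math
from typing import Mapping

from .deck import DeckValidationError, MortalityInputs, RiskCoefficientSet

__all__ = [
    "MissingCovariateError",
    "build_covariates",
    "annual_risk",
    "annualize",
    "bmi_mortality_hr",
    "life_table_q",
    "all_cause_mortality",
]


class MissingCovariateError(DeckValidationError):
    pass


def build_covariates(age: float, fraction_female: float, bmi: float, sbp: float,
                     tc: float, hdl: float, hba1c: float, smoker: float,
                     prediabetes: float = 0.0, diabetes: float = 0.0) -> dict[str, float]:
    """Centred covariates from raw risk-factor values."""
    return {
        "age_c": age - 50.0,
        "female": fraction_female,
        "bmi_c": bmi - 25.0,
        "sbp_c": sbp - 120.0,
        "tchdl_c": (tc / hdl if hdl > 0 else 0.0) - 4.0,
        "hba1c_c": hba1c - 5.5,
        "smoker": smoker,
        "prediabetes": prediabetes,
        "diabetes": diabetes,
    }


def annualize(prob: float, horizon_years: int) -> float:
    """Convert a multi-year risk to an annual probability assuming a
    constant hazard: ``q1 = 1 − (1 − qH)^(1/H)``."""
    if horizon_years <= 1:
        return prob
    return 1.0 - (1.0 - min(prob, 1.0)) ** (1.0 / horizon_years)


def annual_risk(equation: str, profile: Mapping[str, float], coefficients: RiskCoefficientSet) -> float:
    """Annual probability from a named equation evaluated on ``profile``."""
    if equation not in coefficients.equations:
        raise DeckValidationError(f"unknown risk equation {equation!r}")
    eq = coefficients.equations[equation]
    lp = 0.0
    for cov, beta in eq.coefficients.items():
        if cov not in profile:
            raise MissingCovariateError(f"equation {equation!r}: missing covariate {cov!r}")
        lp += beta * profile[cov]
    if eq.form == "logistic":
        p = 1.0 / (1.0 + math.exp(-(eq.intercept + lp)))
    else:  # hazard form
        p = 1.0 - math.exp(-eq.intercept * math.exp(lp))
    p = annualize(p, eq.horizon_years)
    return min(max(p, 0.0), 1.0)


def bmi_mortality_hr(bmi: float, inputs: MortalityInputs) -> float:
    """Hazard ratio ``hr_per_unit^(BMI − reference)``; 1 at the reference."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    return inputs.hr_bmi_per_unit ** (bmi - inputs.reference_bmi)


def life_table_q(inputs: MortalityInputs, age: float, fraction_female: float) -> float:
    """Sex-weighted all-cause annual death probability; ages beyond the
    table use the terminal row."""
    ages = sorted(inputs.life_table)
    a = int(age)
    if a < ages[0]:
        a = ages[0]
    elif a > ages[-1]:
        a = ages[-1]
    elif a not in inputs.life_table:
        a = max(x for x in ages if x <= a)
    row = inputs.life_table[a]
    return fraction_female * row["female"] + (1.0 - fraction_female) * row["male"]


def _state_hr(occupancy: Mapping[str, float], post_state_hrs: Mapping[str, float]) -> float:
    """Mean-cohort post-state hazard ratio: per state a linear-in-occupancy
    factor ``1 + occ·(HR − 1)``, combined multiplicatively over states."""
    hr = 1.0
    for state, state_hr in post_state_hrs.items():
        occ = occupancy.get(state, 0.0)
        hr *= 1.0 + occ * (state_hr - 1.0)
    return hr


def all_cause_mortality(age: float, fraction_female: float, bmi_for_hr: float,
                        occupancy: Mapping[str, float], inputs: MortalityInputs,
                        event_rates: Mapping[str, float] | None = None) -> float:
    """Per-cycle death probability.

    ``q = 1 − (1 − q_bg·HR_bmi·HR_states) · Π_e (1 − rate_e·CF_e·HR_bmi)``
    with ``q_bg`` the cause-deleted life-table probability; clamped to [0,1].
    """
    q_bg = life_table_q(inputs, age, fraction_female) * (1.0 - inputs.cause_deduction)
    hr_bmi = bmi_mortality_hr(bmi_for_hr, inputs)
    hr_states = _state_hr(occupancy, inputs.post_state_hrs)
    surv = 1.0 - min(q_bg * hr_bmi * hr_states, 1.0)
    for event, rate in (event_rates or {}).items():
        cf = inputs.case_fatalities.get(event, 0.0)
        surv *= 1.0 - min(rate * cf * hr_bmi, 1.0)
    return min(max(1.0 - surv, 0.0), 1.0)
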