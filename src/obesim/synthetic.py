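"""Default input decks and fixtures.

The base-case cohort, discounting, catch-up and analysis settings are
pinned to the published study conditions (age 50, BMI 37.5 kg/m², 67%
female, glycemic mix 26.0/46.4/27.6%, HbA1c 8.1% in the T2D subcohort,
54%/100% post-cessation catch-up, 12.7% prediabetes return, 1.5% annual
discounting, 40-year horizon, WTP CAD 50 000, bariatric threshold
35 kg/m², 2-year treatment duration, 1000 PSA iterations).  Everything
else — life table, risk-equation coefficients, cost and disutility tables,
arm effect sizes — is a synthetic fill with literature-plausible signs and
magnitudes; no fidelity to the unpublished supplementary inputs is
claimed.  The synthetic arm effects preserve the published weight-loss
ordering semaglutide > liraglutide > NB-32 > orlistat > diet-and-exercise.
"""

from __future__ import annotations

import math

from .cea import CEPoint
from .deck import (
    ACUTE_EVENTS,
    GLYCEMIC_SUBGROUPS,
    BariatricBlock,
    CatchupSchedule,
    CohortProfile,
    ConfigurationError,
    CostSet,
    InputDeck,
    MortalityInputs,
    PSAParameter,
    RiskCoefficientSet,
    RiskEquation,
    ScenarioToggles,
    SimulationSettings,
    TreatmentArm,
    UtilityModel,
    get_path,
    set_path,
)

__all__ = ["PINNED", "ARM_ORDER", "default_deck", "random_deck", "table1_fixture", "TABLE1_BLOCKS"]

#: Constants pinned to the published study conditions.
PINNED = {
    "start_age": 50.0,
    "fraction_female": 0.67,
    "bmi": 37.5,
    "glycemic_mix": (0.260, 0.464, 0.276),
    "hba1c_t2d": 8.1,
    "diabetes_duration_t2d": 8.0,
    "catchup_return_rates": [0.54, 1.0],
    "prediabetes_return_rate": 0.127,
    "discount_rate": 0.015,
    "horizon_years": 40,
    "wtp": 50_000.0,
    "bariatric_bmi_threshold": 35.0,
    "treatment_duration": 2,
    "psa_iterations": 1000,
    "retirement_age": 65.0,
}

ARM_ORDER = ["diet_exercise", "orlistat", "nb32", "liraglutide", "semaglutide"]


def _subgroup_deltas(bmi: float, sbp: float, tc: float, hdl: float, hba1c: float,
                     reversal: float) -> dict[str, dict[str, float]]:
    # T2D subgroup: no reversal (absorbing); slightly larger HbA1c response
    out = {}
    for g in GLYCEMIC_SUBGROUPS:
        out[g] = {
            "bmi": bmi, "sbp": sbp, "tc": tc, "hdl": hdl,
            "hba1c": hba1c * (1.5 if g == "t2d" else 1.0),
            "prediabetes_reversal": 0.0 if g == "t2d" else reversal,
        }
    return out


def _life_table() -> dict[int, dict[str, float]]:
    """Gompertz-form synthetic annual death probabilities (non-official)."""
    table = {}
    for age in range(0, 110):
        qf = min(2e-4 + 2.5e-5 * math.exp(0.092 * age), 0.95)
        qm = min(3e-4 + 4.0e-5 * math.exp(0.092 * age), 0.95)
        table[age] = {"female": round(qf, 8), "male": round(qm, 8)}
    return table


def _risk_set() -> RiskCoefficientSet:
    eq = {
        "t2d": RiskEquation("t2d", "hazard", 0.003, {
            "age_c": 0.015, "female": -0.10, "bmi_c": 0.070, "hba1c_c": 0.0,
            "smoker": 0.20, "prediabetes": 2.0,
        }),
        "cvd_primary": RiskEquation("cvd_primary", "hazard", 0.0012, {
            "age_c": 0.065, "female": -0.35, "bmi_c": 0.030, "sbp_c": 0.012,
            "tchdl_c": 0.15, "smoker": 0.50, "diabetes": 0.60,
        }),
        "cvd_recurrent": RiskEquation("cvd_recurrent", "hazard", 0.020, {
            "age_c": 0.030, "bmi_c": 0.020,
        }),
        "sleep_apnea": RiskEquation("sleep_apnea", "logistic", -3.2, {
            "bmi_c": 0.12, "female": -0.50, "age_c": 0.010,
        }),
        "colon_cancer": RiskEquation("colon_cancer", "hazard", 0.0005, {
            "age_c": 0.040, "bmi_c": 0.020,
        }),
        "breast_cancer": RiskEquation("breast_cancer", "hazard", 0.0010, {
            "age_c": 0.010, "bmi_c": 0.015,
        }),
        "endometrial_cancer": RiskEquation("endometrial_cancer", "hazard", 0.0004, {
            "age_c": 0.010, "bmi_c": 0.040,
        }),
        "knee_surgery": RiskEquation("knee_surgery", "hazard", 0.0010, {
            "age_c": 0.030, "bmi_c": 0.060,
        }),
    }
    return RiskCoefficientSet(equations=eq, hba1c_annual_increase=0.05, menopause_age=51.0)


def _cost_set() -> CostSet:
    return CostSet(
        chronic={
            "t2d": {"public": 2500.0, "private": 1500.0, "wpl": 1200.0},
            "sleep_apnea": {"public": 500.0, "private": 800.0, "wpl": 400.0},
            "post_acs": {"public": 2000.0, "private": 500.0, "wpl": 800.0},
            "post_stroke": {"public": 3500.0, "private": 800.0, "wpl": 1500.0},
            "colon_cancer": {"public": 8000.0, "private": 1000.0, "wpl": 2000.0},
            "breast_cancer": {"public": 6000.0, "private": 1000.0, "wpl": 1500.0},
            "endometrial_cancer": {"public": 5000.0, "private": 800.0, "wpl": 1200.0},
            "post_knee_surgery": {"public": 300.0, "private": 200.0, "wpl": 300.0},
        },
        events={
            "mi": {"public": 25000.0, "private": 1000.0, "wpl": 3000.0},
            "ua": {"public": 12000.0, "private": 500.0, "wpl": 1500.0},
            "stroke": {"public": 35000.0, "private": 2000.0, "wpl": 5000.0},
            "tia": {"public": 5000.0, "private": 300.0, "wpl": 500.0},
            "knee_surgery": {"public": 15000.0, "private": 500.0, "wpl": 2000.0},
            "bariatric_surgery": {"public": 18000.0, "private": 2000.0, "wpl": 3000.0},
            "colon_cancer": {"public": 12000.0, "private": 1000.0, "wpl": 2000.0},
            "breast_cancer": {"public": 10000.0, "private": 1000.0, "wpl": 1500.0},
            "endometrial_cancer": {"public": 9000.0, "private": 800.0, "wpl": 1200.0},
        },
        # four annual visits + two annual blood checks
        monitoring={"public": 4 * 100.0 + 2 * 50.0, "private": 0.0, "wpl": 0.0},
        lifestyle={"public": 0.0, "private": 400.0 + 600.0, "wpl": 0.0},
        ae_costs={
            "gi_severe": {"public": 300.0, "private": 50.0, "wpl": 100.0},
            "hypoglycemia": {"public": 150.0, "private": 20.0, "wpl": 50.0},
        },
        drug_payer="private",
    )


def _utility_model() -> UtilityModel:
    # synthetic placeholder regression: complication-free utility ≈ 0.85
    # at the baseline cohort (BMI 37.5, age 50, 67% female)
    return UtilityModel(
        intercept=1.132, coef_bmi=-0.0045, coef_age=-0.002, coef_female=-0.02,
        state_disutilities={
            "t2d": 0.06, "sleep_apnea": 0.04, "post_acs": 0.06, "post_stroke": 0.12,
            "colon_cancer": 0.15, "breast_cancer": 0.10, "endometrial_cancer": 0.10,
            "post_knee_surgery": 0.03,
        },
        event_disutilities={
            "mi": 0.06, "ua": 0.03, "stroke": 0.15, "tia": 0.02,
            "knee_surgery": 0.04, "bariatric_surgery": 0.05,
            "colon_cancer": 0.05, "breast_cancer": 0.04, "endometrial_cancer": 0.04,
        },
        ae_disutilities={"gi_severe": 0.008, "hypoglycemia": 0.004},
    )


# (bmi, sbp, tc, hdl, hba1c, reversal, responder_fraction, annual_drug_cost)
_ARM_SPECS = {
    "diet_exercise": dict(bmi=-0.9, sbp=-1.0, tc=-0.05, hdl=0.01, hba1c=-0.1,
                          reversal=0.10, rf=1.0, cost=0.0,
                          ae={"gi_severe": 0.005}),
    "orlistat": dict(bmi=-1.4, sbp=-1.5, tc=-0.10, hdl=0.01, hba1c=-0.15,
                     reversal=0.15, rf=0.50, cost=1900.0,
                     ae={"gi_severe": 0.05}),
    "nb32": dict(bmi=-1.9, sbp=-0.5, tc=-0.10, hdl=0.02, hba1c=-0.20,
                 reversal=0.20, rf=0.60, cost=2800.0,
                 ae={"gi_severe": 0.04}),
    "liraglutide": dict(bmi=-2.6, sbp=-2.5, tc=-0.12, hdl=0.02, hba1c=-0.35,
                        reversal=0.35, rf=0.75, cost=4500.0,
                        ae={"gi_severe": 0.03, "hypoglycemia": 0.01}),
    "semaglutide": dict(bmi=-5.6, sbp=-3.9, tc=-0.15, hdl=0.03, hba1c=-0.55,
                        reversal=0.50, rf=0.86, cost=5000.0,
                        ae={"gi_severe": 0.03, "hypoglycemia": 0.01}),
}

_MAINTENANCE_RATIO = 0.88  # Week-104 change / Week-68 change, shared by all arms
_DISCONTINUATION = 0.15    # per-cycle rate, active only in trial-product scenarios


def default_deck(seed: int = 0) -> InputDeck:
    """The base-case input deck: pinned study conditions + synthetic fills."""
    de = _ARM_SPECS["diet_exercise"]
    de_deltas = _subgroup_deltas(de["bmi"], de["sbp"], de["tc"], de["hdl"], de["hba1c"], de["reversal"])
    arms = {}
    for name, s in _ARM_SPECS.items():
        arms[name] = TreatmentArm(
            name=name,
            deltas_year1=_subgroup_deltas(s["bmi"], s["sbp"], s["tc"], s["hdl"], s["hba1c"], s["reversal"]),
            responder_fraction=s["rf"],
            nonresponder_deltas=_subgroup_deltas(de["bmi"], de["sbp"], de["tc"], de["hdl"], de["hba1c"], de["reversal"]),
            maintenance_ratio=_MAINTENANCE_RATIO,
            per_cycle_discontinuation=_DISCONTINUATION,
            treatment_duration=PINNED["treatment_duration"],
            annual_drug_cost=s["cost"],
            ae_rates=dict(s["ae"]),
        )
    deck = InputDeck(
        cohort=CohortProfile(
            start_age=PINNED["start_age"], fraction_female=PINNED["fraction_female"],
            bmi=PINNED["bmi"], glycemic_mix=PINNED["glycemic_mix"],
            hba1c_t2d=PINNED["hba1c_t2d"], diabetes_duration_t2d=PINNED["diabetes_duration_t2d"],
        ),
        settings=SimulationSettings(
            horizon_years=PINNED["horizon_years"],
            discount_rate_costs=PINNED["discount_rate"],
            discount_rate_benefits=PINNED["discount_rate"],
            wtp=PINNED["wtp"], retirement_age=PINNED["retirement_age"], seed=seed,
        ),
        toggles=ScenarioToggles(),
        arms=arms,
        catchup=CatchupSchedule(
            return_rates=list(PINNED["catchup_return_rates"]),
            prediabetes_return_rate=PINNED["prediabetes_return_rate"],
            natural_bmi_drift=0.1,
        ),
        risk=_risk_set(),
        mortality=MortalityInputs(
            life_table=_life_table(),
            cause_deduction=0.25,
            hr_bmi_per_unit=1.03,
            reference_bmi=25.0,
            case_fatalities={"mi": 0.05, "ua": 0.02, "stroke": 0.10,
                             "knee_surgery": 0.002, "bariatric_surgery": 0.003},
            post_state_hrs={"post_acs": 1.6, "post_stroke": 1.8, "t2d": 1.4},
        ),
        bariatric=BariatricBlock(bmi_threshold=PINNED["bariatric_bmi_threshold"], uptake=0.05, bmi_delta=-8.0),
        costs=_cost_set(),
        utilities=_utility_model(),
        psa=_psa_parameters(),
        reference_arm="diet_exercise",
    )
    return deck.validate()


def _psa_parameters() -> list[PSAParameter]:
    params: list[PSAParameter] = []
    for arm, s in _ARM_SPECS.items():
        for g in GLYCEMIC_SUBGROUPS:
            params.append(PSAParameter(f"arms.{arm}.deltas_year1.{g}.bmi", se=abs(s["bmi"]) * 0.10, family="normal"))
        if arm != "diet_exercise":
            params.append(PSAParameter(f"arms.{arm}.responder_fraction", se=0.03, family="beta"))
    # chronic cost uncertainty (20% of mean), drawn as gammas
    for state, mean in (("t2d", 2500.0), ("sleep_apnea", 500.0), ("post_acs", 2000.0), ("post_stroke", 3500.0)):
        params.append(PSAParameter(f"costs.chronic.{state}.public", se=mean * 0.2, family="gamma"))
    params.append(PSAParameter("mortality.hr_bmi_per_unit", se=0.005, family="normal"))
    params.append(PSAParameter("utilities.state_disutilities.t2d", se=0.01, family="beta"))
    params.append(PSAParameter("mortality.case_fatalities.mi", se=0.01, family="beta"))
    # de-duplicate (keep the last declaration per path)
    seen: dict[str, PSAParameter] = {p.path: p for p in params}
    return list(seen.values())


def random_deck(seed: int, perturbation_scale: float = 0.1) -> InputDeck:
    """A validating deck with multiplicatively perturbed synthetic fills.

    Pinned constants (cohort, discounting, horizon, catch-up) stay fixed;
    effect sizes, costs, coefficients and hazards are jittered by
    ``1 + scale·u`` with ``u ~ U(−1, 1)``.
    """
    import numpy as np

    if perturbation_scale < 0:
        raise ValueError("perturbation_scale must be >= 0")
    deck = default_deck(seed=seed)
    if perturbation_scale == 0:
        return deck
    rng = np.random.default_rng(seed)
    d = deck.to_dict()

    def jitter(path: str, lo: float | None = None, hi: float | None = None):
        val = get_path(d, path)
        val *= 1.0 + perturbation_scale * float(rng.uniform(-1.0, 1.0))
        if lo is not None:
            val = max(val, lo)
        if hi is not None:
            val = min(val, hi)
        set_path(d, path, val)

    for arm in d["arms"]:
        for g in GLYCEMIC_SUBGROUPS:
            for f in ("bmi", "sbp", "tc", "hdl", "hba1c"):
                jitter(f"arms.{arm}.deltas_year1.{g}.{f}")
            jitter(f"arms.{arm}.deltas_year1.{g}.prediabetes_reversal", 0.0, 1.0)
        jitter(f"arms.{arm}.responder_fraction", 0.0, 1.0)
        jitter(f"arms.{arm}.annual_drug_cost", 0.0)
        jitter(f"arms.{arm}.maintenance_ratio", 0.5, 1.2)
    for eq in d["risk"]["equations"]:
        jitter(f"risk.equations.{eq}.intercept", 0.0 if d["risk"]["equations"][eq]["form"] == "hazard" else None)
    for state in d["costs"]["chronic"]:
        for payer in ("public", "private", "wpl"):
            jitter(f"costs.chronic.{state}.{payer}", 0.0)
    for ev in d["costs"]["events"]:
        jitter(f"costs.events.{ev}.public", 0.0)
    for ev in d["mortality"]["case_fatalities"]:
        jitter(f"mortality.case_fatalities.{ev}", 0.0, 1.0)
    jitter("mortality.hr_bmi_per_unit", 1.0)
    jitter("mortality.cause_deduction", 0.0, 1.0)
    for st in d["utilities"]["state_disutilities"]:
        jitter(f"utilities.state_disutilities.{st}", 0.0, 1.0)
    return InputDeck.from_dict(d).validate()


# ---------------------------------------------------------------------------
# Published Table 1 fixture: printed (cost, QALY) points per analysis block.
# Values are transcribed verbatim (2021 CAD; QALYs as printed); rows are
# (arm, intervention cost, disease cost, total cost, total QALY).
# ---------------------------------------------------------------------------

TABLE1_BLOCKS: dict[str, list[tuple[str, float, float, float, float]]] = {
    "societal": [
        ("diet_exercise", 0, 208_458, 208_458, 18.18),
        ("orlistat", 1_901, 207_551, 209_452, 18.22),
        ("nb32", 3_336, 207_427, 210_763, 18.23),
        ("liraglutide", 5_839, 206_783, 212_622, 18.27),
        ("semaglutide", 6_737, 205_999, 212_736, 18.32),
    ],
    "private": [
        ("diet_exercise", 0, 144_916, 144_916, 18.18),
        ("orlistat", 1_901, 144_558, 146_459, 18.22),
        ("nb32", 3_336, 144_516, 147_852, 18.23),
        ("liraglutide", 5_839, 144_271, 150_110, 18.27),
        ("semaglutide", 6_737, 144_028, 150_765, 18.32),
    ],
    "public": [
        ("diet_exercise", 0, 54_944, 54_944, 18.18),
        ("orlistat", 1_901, 54_531, 56_432, 18.22),
        ("nb32", 3_336, 54_476, 57_812, 18.23),
        ("liraglutide", 5_839, 54_202, 60_041, 18.27),
        ("semaglutide", 6_737, 53_813, 60_550, 18.32),
    ],
    "scenario1": [
        ("diet_exercise", 0, 208_458, 208_458, 18.18),
        ("orlistat", 3_592, 206_948, 210_540, 18.24),
        ("nb32", 6_307, 206_706, 213_013, 18.25),
        ("liraglutide", 7_740, 206_397, 214_137, 18.27),
        ("semaglutide", 8_169, 205_934, 214_103, 18.33),
    ],
    "scenario2": [
        ("diet_exercise", 0, 208_488, 208_488, 18.18),
        ("orlistat", 1_546, 207_732, 209_277, 18.21),
        ("nb32", 3_336, 207_653, 210_989, 18.22),
        ("liraglutide", 5_868, 206_988, 212_855, 18.26),
        ("semaglutide", 6_798, 206_227, 213_025, 18.31),
    ],
    "scenario3": [
        ("liraglutide", 5_301, 179_907, 185_208, 19.391),
        ("semaglutide", 6_530, 178_407, 184_936, 19.479),
    ],
    "scenario4": [
        ("diet_exercise", 0, 208_482, 208_482, 18.16),
        ("orlistat", 1_901, 207_587, 209_488, 18.19),
        ("nb32", 3_335, 207_462, 210_797, 18.19),
        ("liraglutide", 5_837, 206_830, 212_667, 18.21),
        ("semaglutide", 6_734, 206_041, 212_775, 18.24),
    ],
}


def table1_fixture(block: str) -> list[CEPoint]:
    """Printed (total cost, total QALY) points for one analysis block."""
    if block not in TABLE1_BLOCKS:
        raise ConfigurationError(f"unknown Table 1 block {block!r}; available: {sorted(TABLE1_BLOCKS)}")
    return [CEPoint(name, float(total), float(qaly))
            for name, _int, _dis, total, qaly in TABLE1_BLOCKS[block]]


def table1_components(block: str) -> list[tuple[str, float, float, float, float]]:
    """Full printed rows (intervention, disease, total cost, QALY)."""
    if block not in TABLE1_BLOCKS:
        raise ConfigurationError(f"unknown Table 1 block {block!r}")
    return list(TABLE1_BLOCKS[block])
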