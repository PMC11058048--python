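"""Input-deck data model: everything a simulation run consumes.

A deck bundles the cohort baseline profile, the treatment arms (surrogate
endpoint effects by glycemic subgroup), the post-cessation catch-up
schedule, life tables and mortality adjustments, risk-equation coefficient
sets, cost tables by payer, the utility model and the PSA uncertainty
declarations.  Decks serialize to a JSON + CSV bundle so they can be
inspected and edited outside the package.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

__all__ = [
    "DeckValidationError",
    "ConfigurationError",
    "CohortProfile",
    "SimulationSettings",
    "ScenarioToggles",
    "TreatmentArm",
    "CatchupSchedule",
    "RiskEquation",
    "RiskCoefficientSet",
    "MortalityInputs",
    "BariatricBlock",
    "CostSet",
    "UtilityModel",
    "PSAParameter",
    "InputDeck",
    "save_deck",
    "load_deck",
    "get_path",
    "set_path",
]

RISK_FACTORS = ("bmi", "sbp", "tc", "hdl", "hba1c")
GLYCEMIC_SUBGROUPS = ("ngt", "prediabetes", "t2d")
CHRONIC_STATES = (
    "t2d",
    "sleep_apnea",
    "post_acs",
    "post_stroke",
    "colon_cancer",
    "breast_cancer",
    "endometrial_cancer",
    "post_knee_surgery",
)
ACUTE_EVENTS = ("mi", "ua", "stroke", "tia", "knee_surgery", "bariatric_surgery")
PERSPECTIVES = ("public", "private", "societal")


class DeckValidationError(ValueError):
    """Raised when a deck (or one of its parts) violates an invariant."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ConfigurationError(ValueError):
    """Raised for unknown arms, unresolvable parameter paths, etc."""


def _check(cond: bool, msg: str, out: list[str]) -> None:
    if not cond:
        out.append(msg)


@dataclass
class CohortProfile:
    """Mean baseline characteristics of the closed cohort."""

    start_age: float = 50.0
    fraction_female: float = 0.67
    bmi: float = 37.5
    sbp: float = 133.0
    total_cholesterol: float = 4.9
    hdl_cholesterol: float = 1.25
    glycemic_mix: tuple[float, float, float] = (0.260, 0.464, 0.276)
    hba1c_t2d: float = 8.1
    diabetes_duration_t2d: float = 8.0
    smoker_fraction: float = 0.11

    def violations(self) -> list[str]:
        v: list[str] = []
        mix = self.glycemic_mix
        _check(len(mix) == 3, "glycemic_mix must have 3 components", v)
        _check(all(m >= 0 for m in mix), "glycemic_mix components must be non-negative", v)
        _check(abs(sum(mix) - 1.0) <= 1e-9, "glycemic_mix must sum to 1", v)
        _check(self.bmi > 0, "bmi must be positive", v)
        _check(0.0 <= self.fraction_female <= 1.0, "fraction_female must be in [0,1]", v)
        _check(0.0 <= self.smoker_fraction <= 1.0, "smoker_fraction must be in [0,1]", v)
        return v


@dataclass
class SimulationSettings:
    horizon_years: int = 40
    discount_rate_costs: float = 0.015
    discount_rate_benefits: float = 0.015
    wtp: float = 50_000.0
    half_cycle_correction: bool = False
    retirement_age: float = 65.0
    seed: int = 0

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(self.horizon_years >= 1, "horizon_years must be >= 1", v)
        _check(self.discount_rate_costs >= 0, "discount_rate_costs must be >= 0", v)
        _check(self.discount_rate_benefits >= 0, "discount_rate_benefits must be >= 0", v)
        return v


@dataclass
class ScenarioToggles:
    """Structural switches for the scenario analyses.

    ``effect_on_*`` switches, when False, make the corresponding hard
    endpoint insensitive to treatment-induced risk-factor changes (the
    equations then read the untreated reference trajectory).  T2D and
    sleep apnea always respond to weight loss.
    """

    stopping_rule: bool = True
    estimand: str = "treatment_policy"  # or "trial_product"
    discontinuation: bool = False
    bariatric_next_line: bool = False
    effect_on_cancer: bool = True
    effect_on_cvd: bool = True
    effect_on_mortality: bool = True
    effect_on_knee: bool = True

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(
            self.estimand in ("treatment_policy", "trial_product"),
            "estimand must be 'treatment_policy' or 'trial_product'",
            v,
        )
        return v


def _zero_deltas() -> dict[str, float]:
    d = {f: 0.0 for f in RISK_FACTORS}
    d["prediabetes_reversal"] = 0.0
    return d


@dataclass
class TreatmentArm:
    """One intervention's effect profile.

    ``deltas_year1`` holds, per glycemic subgroup, the year-1 change in
    each surrogate endpoint (BMI in kg/m², SBP in mmHg, TC/HDL in mmol/L,
    HbA1c in %-points) plus the proportion of the prediabetes pool
    reverting to normal glucose tolerance.  ``nonresponder_deltas`` is the
    diet-and-exercise effect attributed to early non-responders.
    """

    name: str
    deltas_year1: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: _zero_deltas() for g in GLYCEMIC_SUBGROUPS}
    )
    responder_fraction: float = 1.0
    nonresponder_deltas: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: _zero_deltas() for g in GLYCEMIC_SUBGROUPS}
    )
    maintenance_ratio: float = 1.0
    per_cycle_discontinuation: float = 0.0
    treatment_duration: int = 2
    annual_drug_cost: float = 0.0
    nonresponder_cost_years: float = 0.5
    ae_rates: dict[str, float] = field(default_factory=dict)
    estimand: str = "treatment_policy"

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(0.0 <= self.responder_fraction <= 1.0, f"arm {self.name}: responder_fraction must be in [0,1]", v)
        _check(self.treatment_duration >= 1, f"arm {self.name}: treatment_duration must be >= 1", v)
        _check(self.maintenance_ratio > 0, f"arm {self.name}: maintenance_ratio must be > 0", v)
        _check(0.0 <= self.per_cycle_discontinuation <= 1.0, f"arm {self.name}: per_cycle_discontinuation must be in [0,1]", v)
        _check(self.annual_drug_cost >= 0, f"arm {self.name}: annual_drug_cost must be >= 0", v)
        for table_name, table in (("deltas_year1", self.deltas_year1), ("nonresponder_deltas", self.nonresponder_deltas)):
            for g in GLYCEMIC_SUBGROUPS:
                _check(g in table, f"arm {self.name}: {table_name} missing subgroup {g}", v)
                if g in table:
                    rev = table[g].get("prediabetes_reversal", 0.0)
                    _check(0.0 <= rev <= 1.0, f"arm {self.name}: prediabetes_reversal must be in [0,1]", v)
        for ev, rate in self.ae_rates.items():
            _check(rate >= 0, f"arm {self.name}: AE rate for {ev} must be >= 0", v)
        return v


@dataclass
class CatchupSchedule:
    """Post-cessation regain of treatment-induced surrogate changes.

    ``return_rates`` gives, per year after cessation, the fraction of the
    delta at cessation that has reverted to baseline; the schedule must end
    at 1 (full catch-up).  ``natural_bmi_drift`` is the annual BMI increase
    (kg/m²) applied to the whole cohort once catch-up is complete.
    """

    return_rates: list[float] = field(default_factory=lambda: [0.54, 1.0])
    prediabetes_return_rate: float = 0.127
    natural_bmi_drift: float = 0.1

    def return_rate(self, years_post: int) -> float:
        if years_post < 1:
            raise ValueError("years_post must be >= 1")
        if years_post > len(self.return_rates):
            return 1.0
        return self.return_rates[years_post - 1]

    def violations(self) -> list[str]:
        v: list[str] = []
        rates = self.return_rates
        _check(len(rates) >= 1, "catch-up schedule must have at least one rate", v)
        _check(all(0.0 <= r <= 1.0 for r in rates), "catch-up rates must be in [0,1]", v)
        _check(all(b >= a for a, b in zip(rates, rates[1:])), "catch-up rates must be non-decreasing", v)
        if rates:
            _check(rates[-1] == 1.0, "final catch-up rate must be 1", v)
        _check(0.0 <= self.prediabetes_return_rate <= 1.0, "prediabetes_return_rate must be in [0,1]", v)
        return v


@dataclass
class RiskEquation:
    """A declared-form annual risk equation.

    ``form`` is ``"logistic"`` (``intercept`` is the logit intercept) or
    ``"hazard"`` (``intercept`` is the baseline hazard h0 and the annual
    probability is ``1 − exp(−h0·exp(lp))``).  ``horizon_years > 1``
    declares that the equation returns a multi-year risk which is
    converted to an annual probability under a constant-hazard assumption.
    """

    name: str
    form: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    horizon_years: int = 1

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(self.form in ("logistic", "hazard"), f"equation {self.name}: form must be logistic or hazard", v)
        if self.form == "hazard":
            _check(self.intercept >= 0, f"equation {self.name}: baseline hazard must be >= 0", v)
        _check(self.horizon_years >= 1, f"equation {self.name}: horizon_years must be >= 1", v)
        return v


@dataclass
class RiskCoefficientSet:
    """Named risk equations plus the CVD acute-event split."""

    equations: dict[str, RiskEquation] = field(default_factory=dict)
    cvd_event_split: dict[str, float] = field(
        default_factory=lambda: {"mi": 0.35, "ua": 0.20, "stroke": 0.30, "tia": 0.15}
    )
    hba1c_annual_increase: float = 0.05
    menopause_age: float = 51.0

    def violations(self) -> list[str]:
        v: list[str] = []
        split_sum = sum(self.cvd_event_split.values())
        _check(abs(split_sum - 1.0) <= 1e-9, "cvd_event_split must sum to 1", v)
        _check(all(s >= 0 for s in self.cvd_event_split.values()), "cvd_event_split proportions must be >= 0", v)
        for eq in self.equations.values():
            v.extend(eq.violations())
        return v


@dataclass
class MortalityInputs:
    """Life-table mortality with cause deduction and BMI hazard ratios.

    ``life_table`` maps integer age to ``{"female": q, "male": q}`` annual
    all-cause death probabilities; ages beyond the table use the terminal
    row.  ``cause_deduction`` is the proportion of all-cause deaths
    attributable to the modelled complications (removed so they are not
    double counted).
    """

    life_table: dict[int, dict[str, float]] = field(default_factory=dict)
    cause_deduction: float = 0.25
    hr_bmi_per_unit: float = 1.03
    reference_bmi: float = 25.0
    case_fatalities: dict[str, float] = field(default_factory=dict)
    post_state_hrs: dict[str, float] = field(default_factory=dict)

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(len(self.life_table) > 0, "life_table must be non-empty", v)
        for age, row in self.life_table.items():
            for sex in ("female", "male"):
                q = row.get(sex)
                _check(q is not None and 0.0 <= q <= 1.0, f"life_table q at age {age} ({sex}) must be in [0,1]", v)
        _check(0.0 <= self.cause_deduction <= 1.0, "cause_deduction must be in [0,1]", v)
        _check(self.hr_bmi_per_unit > 0, "hr_bmi_per_unit must be > 0", v)
        for ev, cf in self.case_fatalities.items():
            _check(0.0 <= cf <= 1.0, f"case fatality for {ev} must be in [0,1]", v)
        for st, hr in self.post_state_hrs.items():
            _check(hr >= 0, f"post-state HR for {st} must be >= 0", v)
        return v


@dataclass
class BariatricBlock:
    """Next-line bariatric surgery applied when mean BMI reaches threshold."""

    bmi_threshold: float = 35.0
    uptake: float = 0.05
    bmi_delta: float = -8.0

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(self.bmi_threshold > 0, "bariatric bmi_threshold must be > 0", v)
        _check(0.0 <= self.uptake <= 1.0, "bariatric uptake must be in [0,1]", v)
        return v


def _payer_row(public=0.0, private=0.0, wpl=0.0) -> dict[str, float]:
    return {"public": public, "private": private, "wpl": wpl}


@dataclass
class CostSet:
    """Annual chronic-state costs, one-off event costs, monitoring,
    lifestyle-programme costs and AE costs, split by payer; ``wpl`` rows
    are work-productivity losses (societal perspective only, accrued while
    the cohort is below the retirement age)."""

    chronic: dict[str, dict[str, float]] = field(default_factory=dict)
    events: dict[str, dict[str, float]] = field(default_factory=dict)
    monitoring: dict[str, float] = field(default_factory=lambda: _payer_row())
    lifestyle: dict[str, float] = field(default_factory=lambda: _payer_row())
    ae_costs: dict[str, dict[str, float]] = field(default_factory=dict)
    drug_payer: str = "private"
    currency: str = "2021 CAD"

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(self.drug_payer in ("public", "private"), "drug_payer must be public or private", v)
        for group in (self.chronic, self.events, self.ae_costs):
            for item, row in group.items():
                for payer, amount in row.items():
                    _check(amount >= 0, f"cost {item}/{payer} must be >= 0", v)
        for payer, amount in list(self.monitoring.items()) + list(self.lifestyle.items()):
            _check(amount >= 0, f"cost {payer} must be >= 0", v)
        return v


@dataclass
class UtilityModel:
    """Baseline utility regression (on BMI, age, sex) plus additive
    disutilities for chronic states, acute events and on-treatment AEs."""

    intercept: float = 1.132
    coef_bmi: float = -0.0045
    coef_age: float = -0.002
    coef_female: float = -0.02
    state_disutilities: dict[str, float] = field(default_factory=dict)
    event_disutilities: dict[str, float] = field(default_factory=dict)
    ae_disutilities: dict[str, float] = field(default_factory=dict)

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(self.coef_bmi <= 0, "per-BMI-unit utility coefficient must be <= 0", v)
        for table in (self.state_disutilities, self.event_disutilities, self.ae_disutilities):
            for item, d in table.items():
                _check(d >= 0, f"disutility for {item} must be >= 0", v)
        return v


@dataclass
class PSAParameter:
    """One uncertain parameter: a dot-path into the deck, its SE and the
    distribution family (normal / gamma / beta, moment-matched)."""

    path: str
    se: float
    family: str = "normal"

    def violations(self) -> list[str]:
        v: list[str] = []
        _check(self.family in ("normal", "gamma", "beta"), f"PSA family for {self.path} must be normal/gamma/beta", v)
        _check(self.se >= 0, f"PSA SE for {self.path} must be >= 0", v)
        return v


@dataclass
class InputDeck:
    cohort: CohortProfile = field(default_factory=CohortProfile)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    toggles: ScenarioToggles = field(default_factory=ScenarioToggles)
    arms: dict[str, TreatmentArm] = field(default_factory=dict)
    catchup: CatchupSchedule = field(default_factory=CatchupSchedule)
    risk: RiskCoefficientSet = field(default_factory=RiskCoefficientSet)
    mortality: MortalityInputs = field(default_factory=MortalityInputs)
    bariatric: BariatricBlock = field(default_factory=BariatricBlock)
    costs: CostSet = field(default_factory=CostSet)
    utilities: UtilityModel = field(default_factory=UtilityModel)
    psa: list[PSAParameter] = field(default_factory=list)
    reference_arm: str = "diet_exercise"

    def violations(self) -> list[str]:
        v: list[str] = []
        for part in (self.cohort, self.settings, self.toggles, self.catchup, self.risk,
                     self.mortality, self.bariatric, self.costs, self.utilities):
            v.extend(part.violations())
        for name, arm in self.arms.items():
            _check(name == arm.name, f"arm key {name!r} disagrees with arm.name {arm.name!r}", v)
            v.extend(arm.violations())
        _check(self.reference_arm in self.arms, f"reference_arm {self.reference_arm!r} not among arms", v)
        for p in self.psa:
            v.extend(p.violations())
        return v

    def validate(self) -> "InputDeck":
        v = self.violations()
        if v:
            raise DeckValidationError(v)
        return self

    def arm(self, name: str) -> TreatmentArm:
        if name not in self.arms:
            raise ConfigurationError(f"unknown arm {name!r}; available: {sorted(self.arms)}")
        return self.arms[name]

    # ---- dict round trip ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def plain(obj):
            if isinstance(obj, dict):
                return {str(k): plain(x) for k, x in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(x) for x in obj]
            return obj

        d: dict[str, Any] = {
            "cohort": {**self.cohort.__dict__, "glycemic_mix": list(self.cohort.glycemic_mix)},
            "settings": dict(self.settings.__dict__),
            "toggles": dict(self.toggles.__dict__),
            "arms": {name: plain(arm.__dict__) for name, arm in self.arms.items()},
            "catchup": plain(self.catchup.__dict__),
            "risk": {
                "equations": {n: plain(eq.__dict__) for n, eq in self.risk.equations.items()},
                "cvd_event_split": dict(self.risk.cvd_event_split),
                "hba1c_annual_increase": self.risk.hba1c_annual_increase,
                "menopause_age": self.risk.menopause_age,
            },
            "mortality": plain(self.mortality.__dict__),
            "bariatric": dict(self.bariatric.__dict__),
            "costs": plain(self.costs.__dict__),
            "utilities": plain(self.utilities.__dict__),
            "psa": [dict(p.__dict__) for p in self.psa],
            "reference_arm": self.reference_arm,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "InputDeck":
        cohort = d.get("cohort", {})
        cohort = CohortProfile(**{**cohort, "glycemic_mix": tuple(cohort.get("glycemic_mix", (0.26, 0.464, 0.276)))})
        risk_d = d.get("risk", {})
        risk = RiskCoefficientSet(
            equations={n: RiskEquation(**eq) for n, eq in risk_d.get("equations", {}).items()},
            cvd_event_split=dict(risk_d.get("cvd_event_split", {"mi": 0.35, "ua": 0.2, "stroke": 0.3, "tia": 0.15})),
            hba1c_annual_increase=risk_d.get("hba1c_annual_increase", 0.05),
            menopause_age=risk_d.get("menopause_age", 51.0),
        )
        mort_d = dict(d.get("mortality", {}))
        mort_d["life_table"] = {int(a): dict(row) for a, row in mort_d.get("life_table", {}).items()}
        return cls(
            cohort=cohort,
            settings=SimulationSettings(**d.get("settings", {})),
            toggles=ScenarioToggles(**d.get("toggles", {})),
            arms={name: TreatmentArm(**arm) for name, arm in d.get("arms", {}).items()},
            catchup=CatchupSchedule(**d.get("catchup", {})),
            risk=risk,
            mortality=MortalityInputs(**mort_d),
            bariatric=BariatricBlock(**d.get("bariatric", {})),
            costs=CostSet(**d.get("costs", {})),
            utilities=UtilityModel(**d.get("utilities", {})),
            psa=[PSAParameter(**p) for p in d.get("psa", [])],
            reference_arm=d.get("reference_arm", "diet_exercise"),
        )

    def copy(self) -> "InputDeck":
        return InputDeck.from_dict(self.to_dict())


# ---------------------------------------------------------------------------
# Dot-path access (used by DSA and PSA to perturb single parameters)
# ---------------------------------------------------------------------------

def _walk(d: Any, parts: list[str], path: str):
    node = d
    for part in parts[:-1]:
        if isinstance(node, dict):
            if part not in node:
                raise ConfigurationError(f"path {path!r}: key {part!r} not found")
            node = node[part]
        elif isinstance(node, list):
            try:
                node = node[int(part)]
            except (ValueError, IndexError):
                raise ConfigurationError(f"path {path!r}: bad list index {part!r}") from None
        else:
            raise ConfigurationError(f"path {path!r}: cannot descend into {type(node).__name__}")
    return node


def get_path(deck_dict: dict[str, Any], path: str) -> Any:
    parts = path.split(".")
    node = _walk(deck_dict, parts, path)
    leaf = parts[-1]
    if isinstance(node, dict):
        if leaf not in node:
            raise ConfigurationError(f"path {path!r}: key {leaf!r} not found")
        return node[leaf]
    if isinstance(node, list):
        try:
            return node[int(leaf)]
        except (ValueError, IndexError):
            raise ConfigurationError(f"path {path!r}: bad list index {leaf!r}") from None
    raise ConfigurationError(f"path {path!r}: cannot index into {type(node).__name__}")


def set_path(deck_dict: dict[str, Any], path: str, value: Any) -> None:
    parts = path.split(".")
    node = _walk(deck_dict, parts, path)
    leaf = parts[-1]
    if isinstance(node, dict):
        if leaf not in node:
            raise ConfigurationError(f"path {path!r}: key {leaf!r} not found")
        node[leaf] = value
    elif isinstance(node, list):
        try:
            node[int(leaf)] = value
        except (ValueError, IndexError):
            raise ConfigurationError(f"path {path!r}: bad list index {leaf!r}") from None
    else:
        raise ConfigurationError(f"path {path!r}: cannot index into {type(node).__name__}")


# ---------------------------------------------------------------------------
# Serialization: deck.json plus CSV tables for life table / equations / costs
# ---------------------------------------------------------------------------

def _fmt(x: Any) -> str:
    return repr(float(x)) if isinstance(x, (int, float)) and not isinstance(x, bool) else str(x)


def _life_table_csv(mort: MortalityInputs) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["age", "q_female", "q_male"])
    for age in sorted(mort.life_table):
        row = mort.life_table[age]
        w.writerow([age, _fmt(row["female"]), _fmt(row["male"])])
    return buf.getvalue()


def _equations_csv(risk: RiskCoefficientSet) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["equation", "form", "intercept", "horizon_years", "covariate", "coefficient"])
    for name in sorted(risk.equations):
        eq = risk.equations[name]
        if not eq.coefficients:
            w.writerow([name, eq.form, _fmt(eq.intercept), eq.horizon_years, "", ""])
        for cov in sorted(eq.coefficients):
            w.writerow([name, eq.form, _fmt(eq.intercept), eq.horizon_years, cov, _fmt(eq.coefficients[cov])])
    return buf.getvalue()


def _costs_csv(costs: CostSet) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["category", "item", "public", "private", "wpl"])
    for category, table in (("chronic", costs.chronic), ("event", costs.events), ("ae", costs.ae_costs)):
        for item in sorted(table):
            row = table[item]
            w.writerow([category, item, _fmt(row.get("public", 0.0)), _fmt(row.get("private", 0.0)), _fmt(row.get("wpl", 0.0))])
    w.writerow(["monitoring", "monitoring", _fmt(costs.monitoring.get("public", 0.0)), _fmt(costs.monitoring.get("private", 0.0)), _fmt(costs.monitoring.get("wpl", 0.0))])
    w.writerow(["lifestyle", "lifestyle", _fmt(costs.lifestyle.get("public", 0.0)), _fmt(costs.lifestyle.get("private", 0.0)), _fmt(costs.lifestyle.get("wpl", 0.0))])
    return buf.getvalue()


def _disutilities_csv(util: UtilityModel) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["kind", "item", "disutility"])
    for kind, table in (("state", util.state_disutilities), ("event", util.event_disutilities), ("ae", util.ae_disutilities)):
        for item in sorted(table):
            w.writerow([kind, item, _fmt(table[item])])
    return buf.getvalue()


def serialize_deck(deck: InputDeck) -> dict[str, str]:
    """Serialize to a {filename: text} bundle (stable, byte-reproducible)."""
    d = deck.to_dict()
    # the CSV side-tables carry these; keep deck.json free of duplicates
    d["mortality"] = {k: v for k, v in d["mortality"].items() if k != "life_table"}
    d["risk"] = {k: v for k, v in d["risk"].items() if k != "equations"}
    d["costs"] = {k: v for k, v in d["costs"].items() if k not in ("chronic", "events", "ae_costs", "monitoring", "lifestyle")}
    d["utilities"] = {k: v for k, v in d["utilities"].items()
                      if k not in ("state_disutilities", "event_disutilities", "ae_disutilities")}
    return {
        "deck.json": json.dumps(d, indent=2, sort_keys=True) + "\n",
        "life_table.csv": _life_table_csv(deck.mortality),
        "risk_equations.csv": _equations_csv(deck.risk),
        "costs.csv": _costs_csv(deck.costs),
        "disutilities.csv": _disutilities_csv(deck.utilities),
    }


def save_deck(deck: InputDeck, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for fname, text in serialize_deck(deck).items():
        (directory / fname).write_text(text)
    return directory


def _parse_life_table(text: str) -> dict[int, dict[str, float]]:
    rows = list(csv.DictReader(io.StringIO(text)))
    return {int(r["age"]): {"female": float(r["q_female"]), "male": float(r["q_male"])} for r in rows}


def _parse_equations(text: str) -> dict[str, RiskEquation]:
    eqs: dict[str, RiskEquation] = {}
    for r in csv.DictReader(io.StringIO(text)):
        name = r["equation"]
        if name not in eqs:
            eqs[name] = RiskEquation(name=name, form=r["form"], intercept=float(r["intercept"]),
                                     horizon_years=int(r["horizon_years"]))
        if r["covariate"]:
            eqs[name].coefficients[r["covariate"]] = float(r["coefficient"])
    return eqs


def load_deck(directory: str | Path) -> InputDeck:
    directory = Path(directory)
    d = json.loads((directory / "deck.json").read_text())
    d.setdefault("mortality", {})["life_table"] = _parse_life_table((directory / "life_table.csv").read_text())
    d.setdefault("risk", {})["equations"] = {
        n: eq.__dict__ for n, eq in _parse_equations((directory / "risk_equations.csv").read_text()).items()
    }
    costs = d.setdefault("costs", {})
    chronic: dict[str, dict[str, float]] = {}
    events: dict[str, dict[str, float]] = {}
    ae: dict[str, dict[str, float]] = {}
    monitoring = _payer_row()
    lifestyle = _payer_row()
    for r in csv.DictReader(io.StringIO((directory / "costs.csv").read_text())):
        row = {"public": float(r["public"]), "private": float(r["private"]), "wpl": float(r["wpl"])}
        if r["category"] == "chronic":
            chronic[r["item"]] = row
        elif r["category"] == "event":
            events[r["item"]] = row
        elif r["category"] == "ae":
            ae[r["item"]] = row
        elif r["category"] == "monitoring":
            monitoring = row
        elif r["category"] == "lifestyle":
            lifestyle = row
    costs.update(chronic=chronic, events=events, ae_costs=ae, monitoring=monitoring, lifestyle=lifestyle)
    util = d.setdefault("utilities", {})
    state_d: dict[str, float] = {}
    event_d: dict[str, float] = {}
    ae_d: dict[str, float] = {}
    for r in csv.DictReader(io.StringIO((directory / "disutilities.csv").read_text())):
        {"state": state_d, "event": event_d, "ae": ae_d}[r["kind"]][r["item"]] = float(r["disutility"])
    util.update(state_disutilities=state_d, event_disutilities=event_d, ae_disutilities=ae_d)
    return InputDeck.from_dict(d)
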