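"""Incremental cost-effectiveness analytics.

Builds the efficiency frontier (strict dominance removed first, then
extended dominance iterated to a fixed point so pairwise ICURs increase
along the frontier), computes ICURs and net monetary benefit, and runs the
deterministic (tornado) and probabilistic sensitivity analyses with
CEAC/CEAF summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import run_simulation
from .deck import ConfigurationError, DeckValidationError, InputDeck, get_path, set_path

__all__ = [
    "CEPoint",
    "FrontierRow",
    "FrontierResult",
    "UndefinedICURError",
    "icur",
    "nmb",
    "build_frontier",
    "one_way_dsa",
    "PSACloud",
    "run_psa",
    "ceac_ceaf",
    "psa_convergence",
]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class CEPoint:
    name: str
    total_cost: float
    total_qaly: float


class UndefinedICURError(ValueError):
    pass


def icur(frm: CEPoint, to: CEPoint) -> float:
    """Incremental cost-utility ratio Δcost/ΔQALY from ``frm`` to ``to``.

    The sign convention: a negative ratio with ΔQALY > 0 means ``to``
    saves money while gaining QALYs (dominant); equal-QALY pairs are
    rejected as undefined.
    """
    dq = to.total_qaly - frm.total_qaly
    if dq == 0:
        raise UndefinedICURError(f"ICUR undefined: {frm.name} and {to.name} have equal QALYs")
    return (to.total_cost - frm.total_cost) / dq


def nmb(point: CEPoint, wtp: float) -> float:
    """Net monetary benefit ``wtp·QALY − cost``."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * point.total_qaly - point.total_cost


@dataclass
class FrontierRow:
    name: str
    total_cost: float
    total_qaly: float
    classification: str  # on_frontier / dominated / extendedly_dominated / reference
    incr_cost: float | None = None
    incr_qaly: float | None = None
    icur_next: float | str | None = None
    icur_vs_reference: float | str | None = None


@dataclass
class FrontierResult:
    rows: list[FrontierRow]
    frontier: list[str]
    reference: str

    def classification(self, name: str) -> str:
        return self._row(name).classification

    def _row(self, name: str) -> FrontierRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def _strictly_dominated(p: CEPoint, others: list[CEPoint]) -> bool:
    for q in others:
        if q is p:
            continue
        if (q.total_cost <= p.total_cost and q.total_qaly >= p.total_qaly
                and (q.total_cost < p.total_cost or q.total_qaly > p.total_qaly)):
            return True
    return False


def build_frontier(points: list[CEPoint], reference: str) -> FrontierResult:
    """Classify alternatives and build the increasing-ICUR frontier.

    Strictly dominated points are removed first; extended dominance is
    then removed iteratively until the pairwise ICURs along the surviving
    QALY-ordered set strictly increase.  Exact (cost, QALY) duplicates
    keep the lexicographically first name.
    """
    names = [p.name for p in points]
    if len(set(names)) != len(names):
        raise DeckValidationError("duplicate names among CE points")
    if reference not in names:
        raise ConfigurationError(f"reference {reference!r} not among points")

    classification: dict[str, str] = {}
    for p in points:
        if _strictly_dominated(p, points):
            classification[p.name] = DOMINATED
    # exact duplicates: keep the lexicographically first
    for p in points:
        if p.name in classification:
            continue
        for q in points:
            if (q.name != p.name and q.name not in classification
                    and q.total_cost == p.total_cost and q.total_qaly == p.total_qaly
                    and q.name < p.name):
                classification[p.name] = DOMINATED

    survivors = sorted((p for p in points if p.name not in classification),
                       key=lambda p: (p.total_qaly, p.total_cost))
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for j in range(1, len(survivors) - 1):
            icer_in = icur(survivors[j - 1], survivors[j])
            icer_out = icur(survivors[j], survivors[j + 1])
            if icer_in >= icer_out:
                classification[survivors[j].name] = "extendedly_dominated"
                survivors.pop(j)
                changed = True
                break

    frontier = [p.name for p in survivors]
    ref_point = next(p for p in points if p.name == reference)
    by_name = {p.name: p for p in points}

    rows: list[FrontierRow] = []
    for p in sorted(points, key=lambda p: (p.total_qaly, p.total_cost)):
        cls = classification.get(p.name, "on_frontier")
        if p.name == reference:
            cls = "reference" if p.name in frontier else cls
        row = FrontierRow(p.name, p.total_cost, p.total_qaly, cls)
        if p.name in frontier:
            i = frontier.index(p.name)
            if i > 0:
                prev = by_name[frontier[i - 1]]
                row.incr_cost = p.total_cost - prev.total_cost
                row.incr_qaly = p.total_qaly - prev.total_qaly
                val = icur(prev, p)
                row.icur_next = DOMINANT if (val < 0 and row.incr_qaly > 0) else val
        if p.name != reference:
            dq = p.total_qaly - ref_point.total_qaly
            dc = p.total_cost - ref_point.total_cost
            if dq == 0:
                row.icur_vs_reference = None
            elif dc < 0 and dq > 0:
                row.icur_vs_reference = DOMINANT
            elif dc > 0 and dq < 0:
                row.icur_vs_reference = DOMINATED
            else:
                row.icur_vs_reference = dc / dq
        rows.append(row)
    return FrontierResult(rows=rows, frontier=frontier, reference=reference)


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------

def _arm_point(deck: InputDeck, arm: str, perspective: str) -> CEPoint:
    res = run_simulation(deck, arm)
    return CEPoint(arm, res.total_cost(perspective), res.qaly["discounted"])


def _comparison_icur(deck: InputDeck, intervention: str, comparator: str,
                     perspective: str) -> tuple[float, bool]:
    """ICUR of intervention vs comparator; when one arm dominates, the
    NMB-difference-at-WTP equivalent is substituted and flagged."""
    a = _arm_point(deck, comparator, perspective)
    b = _arm_point(deck, intervention, perspective)
    dq = b.total_qaly - a.total_qaly
    dc = b.total_cost - a.total_cost
    if dq > 0 and dc >= 0:
        return dc / dq, False
    return nmb(b, deck.settings.wtp) - nmb(a, deck.settings.wtp), True


def one_way_dsa(deck: InputDeck, param_specs: list[tuple[str, float, float]],
                intervention: str, comparator: str,
                perspective: str = "societal", top_n: int = 15) -> pd.DataFrame:
    """One-way DSA: re-run the deterministic model at each parameter's low
    and high value and rank parameters by ICUR spread (tornado order)."""
    base_dict = deck.to_dict()
    records = []
    for path, low, high in param_specs:
        get_path(base_dict, path)  # raises ConfigurationError if unresolvable
        results = {}
        for bound, value in (("low", low), ("high", high)):
            d = deck.copy().to_dict()
            set_path(d, path, value)
            results[bound] = _comparison_icur(InputDeck.from_dict(d).validate(),
                                              intervention, comparator, perspective)
        (icur_low, flag_lo), (icur_high, flag_hi) = results["low"], results["high"]
        records.append({
            "parameter": path, "low": low, "high": high,
            "icur_low": icur_low, "icur_high": icur_high,
            "spread": abs(icur_high - icur_low),
            "dominance_flagged": flag_lo or flag_hi,
        })
    frame = pd.DataFrame(records).sort_values("spread", ascending=False, kind="mergesort")
    frame = frame.reset_index(drop=True)
    frame["top15"] = frame.index < top_n
    return frame


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSACloud:
    """Per-iteration (cost, QALY) draws for every arm."""

    draws: pd.DataFrame  # columns: iteration, arm, cost, qaly
    seed: int
    n: int
    perspective: str = "societal"

    def arm_names(self) -> list[str]:
        return sorted(self.draws["arm"].unique())


def _draw(rng: np.random.Generator, mean: float, se: float, family: str) -> float:
    if se == 0.0:
        return mean
    if family == "normal":
        return float(rng.normal(mean, se))
    if family == "gamma":
        if mean <= 0:
            return float(rng.normal(mean, se))
        shape = (mean / se) ** 2
        return float(rng.gamma(shape, se**2 / mean))
    if family == "beta":
        m = min(max(mean, 1e-9), 1 - 1e-9)
        var = se**2
        nu = m * (1 - m) / var - 1.0
        if nu <= 0:  # SE too large for a beta; fall back to clipped normal
            return float(min(max(rng.normal(mean, se), 0.0), 1.0))
        return float(rng.beta(m * nu, (1 - m) * nu))
    raise DeckValidationError(f"unknown PSA family {family!r}")


def run_psa(deck: InputDeck, n: int, seed: int, perspective: str = "societal") -> PSACloud:
    """Monte-Carlo parameter uncertainty: ``n`` draws of every declared
    uncertain parameter, each followed by a full deterministic run per arm."""
    if n < 1:
        raise DeckValidationError("PSA requires n >= 1")
    for p in deck.psa:
        if p.se is None:
            raise DeckValidationError(f"PSA parameter {p.path} lacks an SE")
    rng = np.random.default_rng(seed)
    records = []
    base = deck.to_dict()
    for i in range(n):
        d = InputDeck.from_dict(base).to_dict()
        for p in deck.psa:
            mean = get_path(base, p.path)
            set_path(d, p.path, _draw(rng, float(mean), p.se, p.family))
        it_deck = InputDeck.from_dict(d)
        if it_deck.violations():  # redraws would bias; clamp by validation-safe retry
            it_deck = _sanitize(it_deck)
        for arm in deck.arms:
            res = run_simulation(it_deck, arm)
            records.append({"iteration": i, "arm": arm,
                            "cost": res.total_cost(perspective),
                            "qaly": res.qaly["discounted"]})
    return PSACloud(pd.DataFrame.from_records(records), seed=seed, n=n, perspective=perspective)


def _sanitize(deck: InputDeck) -> InputDeck:
    """Clamp out-of-range probabilities/proportions produced by a draw."""
    d = deck.to_dict()
    for name, arm in d["arms"].items():
        arm["responder_fraction"] = min(max(arm["responder_fraction"], 0.0), 1.0)
        arm["per_cycle_discontinuation"] = min(max(arm["per_cycle_discontinuation"], 0.0), 1.0)
        for table in ("deltas_year1", "nonresponder_deltas"):
            for g, row in arm[table].items():
                if "prediabetes_reversal" in row:
                    row["prediabetes_reversal"] = min(max(row["prediabetes_reversal"], 0.0), 1.0)
        arm["annual_drug_cost"] = max(arm["annual_drug_cost"], 0.0)
    for ev, cf in d["mortality"]["case_fatalities"].items():
        d["mortality"]["case_fatalities"][ev] = min(max(cf, 0.0), 1.0)
    d["mortality"]["hr_bmi_per_unit"] = max(d["mortality"]["hr_bmi_per_unit"], 1e-6)
    return InputDeck.from_dict(d).validate()


def ceac_ceaf(cloud: PSACloud, wtp_grid: list[float]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Acceptability curves and frontier.

    CEAC: per arm, the fraction of iterations in which it has the highest
    NMB at each WTP (ties go to the cheaper arm, then alphabetically, so
    the fractions sum to 1).  CEAF: the acceptability of the arm with the
    highest mean NMB at each WTP.
    """
    if cloud.draws.empty:
        raise DeckValidationError("empty PSA cloud")
    arms = cloud.arm_names()
    wide_c = cloud.draws.pivot(index="iteration", columns="arm", values="cost")[arms]
    wide_q = cloud.draws.pivot(index="iteration", columns="arm", values="qaly")[arms]
    costs = wide_c.to_numpy()
    qalys = wide_q.to_numpy()
    ceac_rows = []
    ceaf_rows = []
    for wtp in wtp_grid:
        nmb_mat = wtp * qalys - costs
        best = nmb_mat.max(axis=1, keepdims=True)
        is_best = nmb_mat >= best - 1e-9
        # tie-break: cheapest among the tied, then first alphabetically
        winner_idx = np.empty(len(nmb_mat), dtype=int)
        for r in range(len(nmb_mat)):
            tied = np.flatnonzero(is_best[r])
            winner_idx[r] = tied[int(np.argmin(costs[r, tied]))] if len(tied) > 1 else tied[0]
        probs = {arm: float(np.mean(winner_idx == j)) for j, arm in enumerate(arms)}
        ceac_rows.append({"wtp": wtp, **probs})
        mean_nmb = nmb_mat.mean(axis=0)
        best_mean = np.flatnonzero(mean_nmb >= mean_nmb.max() - 1e-9)
        j_star = best_mean[np.argmin(costs.mean(axis=0)[best_mean])] if len(best_mean) > 1 else best_mean[0]
        ceaf_rows.append({"wtp": wtp, "arm": arms[j_star], "probability": probs[arms[j_star]]})
    return pd.DataFrame(ceac_rows).set_index("wtp"), pd.DataFrame(ceaf_rows).set_index("wtp")


def psa_convergence(cloud: PSACloud, intervention: str, comparator: str,
                    rel_tol: float = 0.05) -> int:
    """First iteration count after which the running-mean ICUR stays within
    ``rel_tol`` of its final value (a stabilization diagnostic)."""
    piv_c = cloud.draws.pivot(index="iteration", columns="arm", values="cost")
    piv_q = cloud.draws.pivot(index="iteration", columns="arm", values="qaly")
    dc = (piv_c[intervention] - piv_c[comparator]).to_numpy()
    dq = (piv_q[intervention] - piv_q[comparator]).to_numpy()
    n = len(dc)
    running = np.cumsum(dc) / np.maximum(np.cumsum(dq), 1e-300)
    final = running[-1]
    band = abs(final) * rel_tol
    inside = np.abs(running - final) <= band
    for k in range(n):
        if inside[k:].all():
            return k + 1
    return n
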