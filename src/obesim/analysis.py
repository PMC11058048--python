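"""Report assembly: ties the engine and the CEA layer into full analyses.

``run_analysis`` executes one analysis (base case, scenario, frontier, DSA
or PSA) on a deck and writes a results bundle: per-arm per-cycle traces
(CSV), an incremental cost-effectiveness table with dominance
classifications (CSV), totals (JSON), and for DSA/PSA the tornado table
and CEAC/CEAF curves plus plots.  All internal computation is at full
floating precision; display rounding (whole currency, QALYs to 2 d.p.) is
applied only at render time, so rendered incremental columns can differ by
±1 from arithmetic on the rounded cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import cea
from .cea import CEPoint, build_frontier, ceac_ceaf, one_way_dsa, run_psa
from .core import SimulationResult, run_simulation
from .deck import ConfigurationError, InputDeck, load_deck, serialize_deck

logger = logging.getLogger("obesim")

__all__ = ["AnalysisConfig", "run_analysis", "incremental_table", "deck_hash"]

ANALYSES = ("base_case", "scenario", "frontier", "dsa", "psa")


@dataclass
class AnalysisConfig:
    deck: InputDeck
    analysis: str = "base_case"
    perspective: str = "societal"
    output_dir: str | Path | None = None
    seed: int = 0
    # scenario toggles (None = keep the deck's setting)
    stopping_rule: bool | None = None
    estimand: str | None = None
    discontinuation: bool | None = None
    bariatric_next_line: bool | None = None
    effect_on_cancer: bool | None = None
    effect_on_cvd: bool | None = None
    effect_on_mortality: bool | None = None
    effect_on_knee: bool | None = None
    # dsa / psa inputs
    dsa_params: list[tuple[str, float, float]] = field(default_factory=list)
    intervention: str = "semaglutide"
    comparator: str = "orlistat"
    psa_n: int = 1000
    wtp_grid: list[float] = field(default_factory=lambda: [w * 5000.0 for w in range(0, 21)])
    make_plots: bool = False

    def resolved_deck(self) -> InputDeck:
        deck = self.deck.copy()
        t = deck.toggles
        for name in ("stopping_rule", "estimand", "discontinuation", "bariatric_next_line",
                     "effect_on_cancer", "effect_on_cvd", "effect_on_mortality", "effect_on_knee"):
            val = getattr(self, name)
            if val is not None:
                setattr(t, name, val)
        return deck.validate()


def deck_hash(deck: InputDeck) -> str:
    payload = "".join(serialize_deck(deck).values()).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def incremental_table(results: dict[str, SimulationResult], reference: str,
                      perspective: str = "societal") -> pd.DataFrame:
    """Table-1-style incremental analysis from per-arm simulation results."""
    points = [CEPoint(name, res.total_cost(perspective), res.qaly["discounted"])
              for name, res in results.items()]
    frontier = build_frontier(points, reference)
    rows = []
    for row in frontier.rows:
        res = results[row.name]
        rows.append({
            "arm": row.name,
            "intervention_cost": res.intervention_cost(perspective),
            "disease_cost": res.disease_cost(perspective),
            "total_cost": row.total_cost,
            "total_qaly": row.total_qaly,
            "incr_cost": row.incr_cost,
            "incr_qaly": row.incr_qaly,
            "icur_next": row.icur_next,
            "icur_vs_reference": row.icur_vs_reference,
            "classification": row.classification,
        })
    return pd.DataFrame(rows)


def render_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: whole currency, QALYs to 2 d.p. (render-time only)."""
    out = table.copy()
    for col in ("intervention_cost", "disease_cost", "total_cost", "incr_cost"):
        out[col] = out[col].map(lambda x: round(x) if isinstance(x, (int, float)) and pd.notna(x) else x)
    for col in ("icur_next", "icur_vs_reference"):
        out[col] = out[col].map(lambda x: round(x) if isinstance(x, (int, float)) and pd.notna(x) else x)
    out["total_qaly"] = out["total_qaly"].map(lambda x: round(x, 2))
    out["incr_qaly"] = out["incr_qaly"].map(lambda x: round(x, 2) if isinstance(x, (int, float)) and pd.notna(x) else x)
    return out


def run_analysis(config: AnalysisConfig) -> dict:
    """Run one analysis and (optionally) write the results bundle."""
    if config.analysis not in ANALYSES:
        raise ConfigurationError(f"unknown analysis {config.analysis!r}; one of {ANALYSES}")
    deck = config.resolved_deck()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    logger.info("analysis=%s seed=%d deck=%s toggles=%s", config.analysis, config.seed,
                deck_hash(deck), deck.toggles.__dict__)

    bundle: dict = {"analysis": config.analysis, "deck_hash": deck_hash(deck), "seed": config.seed}

    if config.analysis in ("base_case", "scenario"):
        results = {name: run_simulation(deck, name) for name in deck.arms}
        table = incremental_table(results, deck.reference_arm, config.perspective)
        bundle["table"] = table
        bundle["results"] = results
        if outdir:
            for name, res in results.items():
                res.trace_frame().to_csv(outdir / f"trace_{name}.csv", index=False)
            render_table(table).to_csv(outdir / "incremental_table.csv", index=False)
            totals = {name: res.totals(config.perspective) for name, res in results.items()}
            (outdir / "totals.json").write_text(json.dumps(totals, indent=2, sort_keys=True))
    elif config.analysis == "frontier":
        results = {name: run_simulation(deck, name) for name in deck.arms}
        points = [CEPoint(n, r.total_cost(config.perspective), r.qaly["discounted"])
                  for n, r in results.items()]
        frontier = build_frontier(points, deck.reference_arm)
        bundle["frontier"] = frontier
        if outdir:
            frontier.to_frame().to_csv(outdir / "frontier.csv", index=False)
    elif config.analysis == "dsa":
        if not config.dsa_params:
            raise ConfigurationError("dsa analysis requires dsa_params")
        tornado = one_way_dsa(deck, config.dsa_params, config.intervention,
                              config.comparator, config.perspective)
        bundle["tornado"] = tornado
        if outdir:
            tornado.to_csv(outdir / "tornado.csv", index=False)
            if config.make_plots:
                _tornado_plot(tornado, outdir / "tornado.png")
    elif config.analysis == "psa":
        cloud = run_psa(deck, config.psa_n, config.seed, config.perspective)
        ceac, ceaf = ceac_ceaf(cloud, config.wtp_grid)
        bundle["cloud"] = cloud
        bundle["ceac"] = ceac
        bundle["ceaf"] = ceaf
        if outdir:
            cloud.draws.to_csv(outdir / "psa_cloud.csv", index=False)
            ceac.to_csv(outdir / "ceac.csv")
            ceaf.to_csv(outdir / "ceaf.csv")
            if config.make_plots:
                _psa_plots(cloud, ceac, deck.reference_arm, outdir)
    return bundle


def _tornado_plot(tornado: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = tornado[tornado["top15"]].iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(top) + 1.5))
    base = (top["icur_low"] + top["icur_high"]) / 2.0
    ax.barh(top["parameter"], top["icur_high"] - top["icur_low"], left=top["icur_low"], color="#4878d0")
    ax.set_xlabel("ICUR (currency per QALY)")
    ax.set_title("One-way sensitivity analysis")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _psa_plots(cloud: cea.PSACloud, ceac: pd.DataFrame, reference: str, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    piv_c = cloud.draws.pivot(index="iteration", columns="arm", values="cost")
    piv_q = cloud.draws.pivot(index="iteration", columns="arm", values="qaly")
    fig, ax = plt.subplots(figsize=(7, 6))
    for arm in piv_c.columns:
        if arm == reference:
            continue
        ax.scatter(piv_q[arm] - piv_q[reference], piv_c[arm] - piv_c[reference], s=6, alpha=0.5, label=arm)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs vs reference")
    ax.set_ylabel("Incremental cost vs reference")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "ce_plane.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    for arm in ceac.columns:
        ax.plot(ceac.index, ceac[arm], label=arm)
    ax.set_xlabel("Willingness to pay (per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "ceac.png", dpi=120)
    plt.close(fig)
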