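import math

import numpy as np
import pandas as pd
import pytest

from obesim.cea import (
    DOMINANT,
    CEPoint,
    PSACloud,
    UndefinedICURError,
    build_frontier,
    ceac_ceaf,
    icur,
    nmb,
    one_way_dsa,
    psa_convergence,
    run_psa,
)
from obesim.deck import ConfigurationError, DeckValidationError
from obesim.synthetic import table1_fixture

from oracles import frontier_oracle


# ---------------------------------------------------------------------------
# ICUR / NMB arithmetic
# ---------------------------------------------------------------------------

def test_icur_direct_division():
    a = CEPoint("a", 208_458.0, 18.18)
    b = CEPoint("b", 208_458.0 + 994.0, 18.18 + 0.0423)
    assert icur(a, b) == pytest.approx(994.0 / 0.0423)


def test_icur_equal_qalys_undefined():
    a = CEPoint("a", 100.0, 10.0)
    b = CEPoint("b", 200.0, 10.0)
    with pytest.raises(UndefinedICURError):
        icur(a, b)


def test_icur_negative_when_cheaper_and_better():
    a = CEPoint("a", 1000.0, 10.0)
    b = CEPoint("b", 729.0, 10.09)
    assert icur(a, b) < 0


def test_nmb_arithmetic():
    p = CEPoint("semaglutide", 212_736.0, 18.32)
    assert nmb(p, 0.0) == -212_736.0
    assert nmb(p, 50_000.0) == pytest.approx(703_264.0)


def test_nmb_ranking_matches_frontier_winner():
    pts = table1_fixture("societal")
    best = max(pts, key=lambda p: nmb(p, 50_000.0))
    fr = build_frontier(pts, "diet_exercise")
    assert best.name in fr.frontier


# ---------------------------------------------------------------------------
# frontier construction
# ---------------------------------------------------------------------------

def test_frontier_base_case_extended_dominance():
    fr = build_frontier(table1_fixture("societal"), "diet_exercise")
    assert fr.frontier == ["diet_exercise", "orlistat", "semaglutide"]
    assert fr.classification("nb32") == "extendedly_dominated"
    assert fr.classification("liraglutide") == "extendedly_dominated"
    sema = fr._row("semaglutide")
    assert sema.incr_cost == pytest.approx(3284.0)
    orl = fr._row("orlistat")
    assert orl.incr_cost == pytest.approx(994.0)
    # ICURs strictly increase along the frontier
    icurs = [r.icur_next for r in fr.rows if r.name in fr.frontier and r.icur_next is not None]
    assert all(b > a for a, b in zip(icurs, icurs[1:]))


def test_frontier_scenario1_strict_dominance():
    fr = build_frontier(table1_fixture("scenario1"), "diet_exercise")
    assert fr.classification("liraglutide") == "dominated"
    assert fr.classification("nb32") == "extendedly_dominated"


def test_frontier_scenario3_dominant_sentinel():
    fr = build_frontier(table1_fixture("scenario3"), "liraglutide")
    sema = fr._row("semaglutide")
    assert sema.icur_vs_reference == DOMINANT
    assert fr.classification("liraglutide") == "dominated"


def test_frontier_two_point_dominance():
    pts = [CEPoint("a", 100.0, 5.0), CEPoint("b", 90.0, 6.0)]
    fr = build_frontier(pts, "a")
    assert fr._row("b").icur_vs_reference == DOMINANT
    assert fr.classification("a") == "dominated"


def test_frontier_duplicate_names_rejected():
    pts = [CEPoint("a", 1.0, 1.0), CEPoint("a", 2.0, 2.0)]
    with pytest.raises(DeckValidationError):
        build_frontier(pts, "a")


def test_frontier_unknown_reference_rejected():
    pts = [CEPoint("a", 1.0, 1.0), CEPoint("b", 2.0, 2.0)]
    with pytest.raises(ConfigurationError):
        build_frontier(pts, "c")


@pytest.mark.parametrize("seed", range(30))
def test_frontier_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    pts = [CEPoint(f"p{i}", float(rng.uniform(0, 1e5)), float(rng.uniform(10, 20)))
           for i in range(n)]
    oracle_frontier, oracle_cls = frontier_oracle(pts)
    fr = build_frontier(pts, pts[0].name)
    assert fr.frontier == oracle_frontier
    for p in pts:
        got = fr.classification(p.name)
        want = oracle_cls[p.name]
        if got == "reference":
            got = "on_frontier"
        assert got == want, f"{p.name}: {got} != {want}"


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_deck():
    from obesim import default_deck

    deck = default_deck()
    deck.settings.horizon_years = 15
    return deck


def test_dsa_inert_parameter_ranked_last(small_deck):
    specs = [
        ("arms.semaglutide.annual_drug_cost", 3000.0, 7000.0),
        ("costs.events.bariatric_surgery.public", 0.0, 40000.0),  # never triggered in base case
    ]
    tornado = one_way_dsa(small_deck, specs, "semaglutide", "diet_exercise")
    assert tornado.iloc[-1]["parameter"] == "costs.events.bariatric_surgery.public"
    assert tornado.iloc[-1]["spread"] == 0.0
    assert tornado.iloc[0]["spread"] > 0.0


def test_dsa_unresolvable_path_raises(small_deck):
    with pytest.raises(ConfigurationError):
        one_way_dsa(small_deck, [("arms.semaglutide.cost_of_tea", 0.0, 1.0)],
                    "semaglutide", "diet_exercise")


def test_dsa_benefit_discount_rate_monotone(small_deck):
    """Discounting benefits harder shrinks incremental QALYs, so the ICUR
    rises monotonically with the benefits discount rate."""
    icurs = []
    for rate in (0.0, 0.015, 0.03):
        d = small_deck.copy()
        d.settings.discount_rate_benefits = rate
        from obesim.cea import _comparison_icur

        val, flagged = _comparison_icur(d, "semaglutide", "diet_exercise", "societal")
        assert not flagged
        icurs.append(val)
    assert icurs[0] < icurs[1] < icurs[2]


def test_dsa_intervention_parameter_isolated_from_comparator(small_deck):
    from obesim.core import run_simulation

    base = run_simulation(small_deck, "diet_exercise").total_cost()
    d = small_deck.copy()
    d.arms["semaglutide"].annual_drug_cost *= 2
    assert run_simulation(d, "diet_exercise").total_cost() == pytest.approx(base)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def test_psa_degenerate_ses_reproduce_deterministic_run(small_deck):
    from obesim.core import run_simulation

    deck = small_deck.copy()
    for p in deck.psa:
        p.se = 0.0
    cloud = run_psa(deck, n=3, seed=11)
    det = {arm: (run_simulation(deck, arm).total_cost(), run_simulation(deck, arm).qaly["discounted"])
           for arm in deck.arms}
    for _, row in cloud.draws.iterrows():
        cost, qaly = det[row["arm"]]
        assert row["cost"] == pytest.approx(cost, rel=1e-12)
        assert row["qaly"] == pytest.approx(qaly, rel=1e-12)


def test_psa_seed_reproducibility(small_deck):
    a = run_psa(small_deck, n=4, seed=7)
    b = run_psa(small_deck, n=4, seed=7)
    pd.testing.assert_frame_equal(a.draws, b.draws)
    c = run_psa(small_deck, n=4, seed=8)
    assert not a.draws.equals(c.draws)


def _normal_cloud(n, seed, mu_a=(1000.0, 10.0), mu_b=(1500.0, 10.05), sd=(200.0, 0.02)):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append({"iteration": i, "arm": "a", "cost": rng.normal(mu_a[0], sd[0]),
                     "qaly": rng.normal(mu_a[1], sd[1])})
        rows.append({"iteration": i, "arm": "b", "cost": rng.normal(mu_b[0], sd[0]),
                     "qaly": rng.normal(mu_b[1], sd[1])})
    return PSACloud(pd.DataFrame(rows), seed=seed, n=n)


def test_ceac_probabilities_sum_to_one():
    cloud = _normal_cloud(500, seed=3)
    ceac, _ = ceac_ceaf(cloud, [0.0, 20_000.0, 50_000.0, 100_000.0])
    sums = ceac.sum(axis=1)
    assert np.allclose(sums, 1.0)


def test_ceac_single_arm_is_certain():
    cloud = _normal_cloud(50, seed=1)
    cloud.draws = cloud.draws[cloud.draws["arm"] == "a"]
    ceac, ceaf = ceac_ceaf(cloud, [0.0, 50_000.0])
    assert (ceac["a"] == 1.0).all()
    assert (ceaf["probability"] == 1.0).all()


def test_ceac_degenerate_cloud_picks_higher_nmb():
    rows = []
    for i in range(10):
        rows.append({"iteration": i, "arm": "a", "cost": 1000.0, "qaly": 10.0})
        rows.append({"iteration": i, "arm": "b", "cost": 1500.0, "qaly": 10.05})
    cloud = PSACloud(pd.DataFrame(rows), seed=0, n=10)
    ceac, _ = ceac_ceaf(cloud, [1_000.0, 50_000.0])
    # at WTP 1000, b's extra QALYs are not worth 500; at 50 000 they are
    assert ceac.loc[1_000.0, "a"] == 1.0
    assert ceac.loc[50_000.0, "b"] == 1.0


def test_ceac_two_arm_monotone_in_wtp():
    cloud = _normal_cloud(2000, seed=5)
    grid = [0.0, 10_000.0, 20_000.0, 50_000.0, 100_000.0]
    ceac, _ = ceac_ceaf(cloud, grid)
    probs = ceac["b"].to_numpy()
    assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


def test_psa_convergence_diagnostic_stabilizes():
    cloud = _normal_cloud(1000, seed=9)
    k = psa_convergence(cloud, "b", "a", rel_tol=0.1)
    assert k < 500


def test_psa_missing_se_rejected(small_deck):
    deck = small_deck.copy()
    deck.psa[0].se = None
    with pytest.raises(DeckValidationError):
        run_psa(deck, n=2, seed=0)
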