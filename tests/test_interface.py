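import csv
import json

import pytest
from click.testing import CliRunner

from obesim.analysis import AnalysisConfig, deck_hash, incremental_table, run_analysis
from obesim.cli import main
from obesim.deck import load_deck, save_deck, serialize_deck
from obesim.synthetic import TABLE1_BLOCKS, default_deck


@pytest.fixture(scope="module")
def fast_deck():
    deck = default_deck()
    deck.settings.horizon_years = 10
    return deck


def test_deck_round_trip_is_byte_identical(tmp_path, fast_deck):
    save_deck(fast_deck, tmp_path / "deck")
    reloaded = load_deck(tmp_path / "deck")
    assert serialize_deck(reloaded) == serialize_deck(fast_deck)
    save_deck(reloaded, tmp_path / "deck2")
    for f in (tmp_path / "deck").iterdir():
        assert (tmp_path / "deck2" / f.name).read_bytes() == f.read_bytes()


def test_base_case_bundle_shape(tmp_path, fast_deck):
    config = AnalysisConfig(deck=fast_deck, analysis="base_case", output_dir=tmp_path / "out")
    bundle = run_analysis(config)
    table = bundle["table"]
    assert len(table) == 5
    assert "classification" in table.columns
    assert set(table["arm"]) == set(fast_deck.arms)
    assert (tmp_path / "out" / "incremental_table.csv").exists()
    assert (tmp_path / "out" / "totals.json").exists()
    for arm in fast_deck.arms:
        assert (tmp_path / "out" / f"trace_{arm}.csv").exists()
    totals = json.loads((tmp_path / "out" / "totals.json").read_text())
    assert set(totals) == set(fast_deck.arms)


def test_analysis_reruns_are_identical(tmp_path, fast_deck):
    out1, out2 = tmp_path / "a", tmp_path / "b"
    for out in (out1, out2):
        run_analysis(AnalysisConfig(deck=fast_deck, analysis="base_case", output_dir=out, seed=3))
    for f in out1.iterdir():
        assert (out2 / f.name).read_bytes() == f.read_bytes()


def test_scenario_toggles_resolve_onto_deck(fast_deck):
    config = AnalysisConfig(deck=fast_deck, analysis="scenario", stopping_rule=False,
                            effect_on_cancer=False)
    resolved = config.resolved_deck()
    assert resolved.toggles.stopping_rule is False
    assert resolved.toggles.effect_on_cancer is False
    assert fast_deck.toggles.stopping_rule is True  # source deck untouched


def test_unknown_analysis_rejected(fast_deck):
    from obesim.deck import ConfigurationError

    with pytest.raises(ConfigurationError):
        run_analysis(AnalysisConfig(deck=fast_deck, analysis="evpi"))


def test_deck_hash_tracks_content(fast_deck):
    h1 = deck_hash(fast_deck)
    other = fast_deck.copy()
    other.arms["semaglutide"].annual_drug_cost += 1.0
    assert deck_hash(other) != h1
    assert deck_hash(fast_deck.copy()) == h1


def _write_points_csv(path, block):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "cost", "qaly"])
        for name, _i, _d, total, qaly in TABLE1_BLOCKS[block]:
            w.writerow([name, total, qaly])


def test_cli_frontier_reproduces_printed_classifications(tmp_path):
    csv_path = tmp_path / "points.csv"
    _write_points_csv(csv_path, "societal")
    runner = CliRunner()
    out_path = tmp_path / "frontier.csv"
    result = runner.invoke(main, ["frontier", str(csv_path), "--reference", "diet_exercise",
                                  "--out", str(out_path)])
    assert result.exit_code == 0, result.output
    rows = {r["name"]: r for r in csv.DictReader(open(out_path))}
    assert rows["nb32"]["classification"] == "extendedly_dominated"
    assert rows["liraglutide"]["classification"] == "extendedly_dominated"
    assert rows["semaglutide"]["classification"] == "on_frontier"
    assert float(rows["semaglutide"]["incr_cost"]) == 3284.0


def test_cli_make_deck_and_run(tmp_path):
    runner = CliRunner()
    deckdir = tmp_path / "deck"
    result = runner.invoke(main, ["make-deck", str(deckdir)])
    assert result.exit_code == 0, result.output
    # shrink the horizon so the CLI run is quick
    deck = load_deck(deckdir)
    deck.settings.horizon_years = 5
    save_deck(deck, deckdir)
    out = tmp_path / "results"
    result = runner.invoke(main, ["run", str(deckdir), "--out", str(out)])
    assert result.exit_code == 0, result.output
    assert (out / "incremental_table.csv").exists()


def test_cli_psa_small(tmp_path):
    runner = CliRunner()
    deckdir = tmp_path / "deck"
    runner.invoke(main, ["make-deck", str(deckdir)])
    deck = load_deck(deckdir)
    deck.settings.horizon_years = 5
    save_deck(deck, deckdir)
    out = tmp_path / "psa"
    result = runner.invoke(main, ["psa", str(deckdir), "--n", "3", "--seed", "1",
                                  "--out", str(out), "--no-plots"])
    assert result.exit_code == 0, result.output
    assert (out / "psa_cloud.csv").exists()
    assert (out / "ceac.csv").exists()


def test_incremental_table_render_rounding(fast_deck):
    from obesim.analysis import render_table
    from obesim.core import run_simulation

    results = {a: run_simulation(fast_deck, a) for a in fast_deck.arms}
    table = incremental_table(results, "diet_exercise")
    rendered = render_table(table)
    for v in rendered["total_cost"]:
        assert v == int(v)
    for v in rendered["total_qaly"]:
        assert round(v, 2) == v
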