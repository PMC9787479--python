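"""Catalysis detection, degrees, rule frequencies and growth fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ironcrn.analytics import (
    GrowthFitError,
    catalysis_percentage,
    catalyzed_species,
    compare,
    degree_metrics,
    format_percent,
    frequency_change,
    growth_fit,
    percent_catalysis,
    rule_frequency,
)
from ironcrn.expansion import ExpansionConfig, expand
from ironcrn.fixtures import make_toy_system
from ironcrn.rules import ReactionEvent


# ---------------------------------------------------------------------------
# Catalysis


def test_identical_networks_have_no_catalyzed_species(chain_net):
    assert catalyzed_species(chain_net, chain_net) == []
    assert percent_catalysis(chain_net, chain_net) == 0.0


def test_catalyzed_requires_membership_in_both(shortcut_nets):
    free, iron = shortcut_nets
    cat = catalyzed_species(free, iron)
    ids = {sp.canonical_id for sp, _, _ in cat}
    assert ids == {"CC(O)C(=O)O"}
    for sp, gen_free, gen_iron in cat:
        assert gen_iron < gen_free
        assert sp.canonical_id in free.species and sp.canonical_id in iron.species


def test_catalysis_is_exactly_the_strict_inequality_set(shortcut_nets):
    free, iron = shortcut_nets
    expected = {
        cid
        for cid, g in free.first_generation.items()
        if cid in iron.first_generation and iron.first_generation[cid] < g
    }
    assert {sp.canonical_id for sp, _, _ in catalyzed_species(free, iron)} == expected


def test_percentage_formatting_follows_report_precision():
    assert format_percent(catalysis_percentage(0, 5)) == "0.0%"
    assert format_percent(catalysis_percentage(1, 4)) == "25%"
    assert format_percent(1.129) == "1.1%"
    assert format_percent(None) == "n/a"
    assert catalysis_percentage(3, 0) is None


# ---------------------------------------------------------------------------
# Degrees


def test_degree_single_event():
    ev = ReactionEvent("r", ("A", "B"), ("C",), 1, False)
    net = _tiny_network(["A", "B", "C"], [ev])
    deg = degree_metrics(net)
    assert deg.loc["A", "out_degree"] == 1 and deg.loc["B", "out_degree"] == 1
    assert deg.loc["C", "in_degree"] == 1
    assert deg["total_degree"].sum() == 3


def test_degree_counts_multiplicity_and_catalysts(shortcut_nets):
    _, iron = shortcut_nets
    deg = degree_metrics(iron)
    # the catalytic Fe3+ gains both an in- and an out-edge from its event
    assert deg.loc["[Fe+3]", "in_degree"] >= 1
    assert deg.loc["[Fe+3]", "out_degree"] >= 1


def test_degree_sums_equal_event_slot_counts(preset_pairs):
    for free, iron in preset_pairs.values():
        for net in (free, iron):
            deg = degree_metrics(net)
            assert deg["in_degree"].sum() == sum(len(e.products) for e in net.events)
            assert deg["out_degree"].sum() == sum(len(e.reactants) for e in net.events)


# ---------------------------------------------------------------------------
# Rule frequencies


def _tiny_network(species_ids, events):
    from ironcrn.expansion import ReactionNetwork
    from ironcrn.molecules import Species

    species = {
        cid: Species(cid, {"C": 1}, 12, 0, False) for cid in species_ids
    }
    return ReactionNetwork(
        config=ExpansionConfig(
            seeds=tuple(species.values()), rules=(), max_generations=1
        ),
        species=species,
        first_generation={cid: 0 for cid in species},
        events=list(events),
        new_species_per_gen={1: 0},
        new_events_per_gen={1: len(events)},
        generations_run=1,
    )


def test_rule_frequency_sums_to_event_count(preset_pairs):
    for free, iron in preset_pairs.values():
        for net in (free, iron):
            freq = rule_frequency(net)
            assert freq.sum() == net.n_events
            assert len(freq) == len(net.config.rules)  # zero rows included


def test_seeds_only_network_has_all_zero_frequencies(chain_toy):
    cfg = ExpansionConfig(
        seeds=chain_toy.config.seeds,
        rules=chain_toy.config.rules,
        max_generations=1,
        mass_cap=59,  # below the dimer: nothing can form
    )
    net = expand(cfg)
    assert rule_frequency(net).sum() == 0


@pytest.mark.parametrize(
    "f_free, f_iron, change",
    [(12, 54, 350), (242, 417, 72), (5, 17, 240), (8739, 10579, 21)],
)
def test_frequency_change_matches_printed_convention(f_free, f_iron, change):
    assert frequency_change(f_free, f_iron) == change


def test_frequency_change_zero_denominator_is_sentinel():
    assert frequency_change(0, 187) is None


@settings(derandomize=True, max_examples=100)
@given(st.integers(1, 10**5), st.integers(0, 10**5))
def test_frequency_change_sign_property(f0, f1):
    change = frequency_change(f0, f1)
    if f1 > f0:
        assert change > 0 or change == 0 and (f1 - f0) * 200 <= f0
    elif f1 == f0:
        assert change == 0
    else:
        assert change <= 0


# ---------------------------------------------------------------------------
# Growth fitting


def test_growth_fit_exact_geometric_series():
    fit = growth_fit([10, 100, 1000], project=[3])
    assert fit["log_slope"] == pytest.approx(1.0)
    assert fit["projections"][3] == pytest.approx(10000.0)


def test_growth_fit_constant_counts():
    fit = growth_fit([7, 7, 7], project=[5])
    assert fit["log_slope"] == pytest.approx(0.0)
    assert fit["projections"][5] == pytest.approx(7.0)


@pytest.mark.parametrize("bad", [[10], [10, 0, 100], []])
def test_growth_fit_errors(bad):
    with pytest.raises(GrowthFitError):
        growth_fit(bad)


def test_projection_overestimates_saturated_network(chain_toy, chain_net):
    """Extrapolating the pre-saturation growth of the chain toy beyond its
    saturation overestimates the true, capped species count — the sense in
    which log-linear projections are upper bounds."""
    counts = chain_net.product_counts_by_generation()
    growing = counts.loc[:2]  # generations 0..2, before saturation
    fit = growth_fit(growing.to_numpy(), generations=growing.index.to_numpy(),
                     project=[4])
    true_count = counts.iloc[-1]  # saturated: 3 species forever
    assert fit["projections"][4] > true_count


@settings(derandomize=True, max_examples=30)
@given(
    st.floats(1.0, 100.0),
    st.floats(0.05, 1.0),
    st.integers(3, 8),
)
def test_growth_fit_recovers_exact_exponentials(c0, slope, n):
    counts = [c0 * 10 ** (slope * g) for g in range(n)]
    fit = growth_fit(counts)
    assert fit["log_slope"] == pytest.approx(slope, rel=1e-6)
    assert 10 ** fit["intercept"] == pytest.approx(c0, rel=1e-6)


# ---------------------------------------------------------------------------
# Full report


def test_compare_report_on_shortcut_toy(shortcut_nets):
    free, iron = shortcut_nets
    report = compare(free, iron)
    assert report.percent_catalysis == pytest.approx(25.0)
    assert list(report.catalyzed["species"]) == ["CC(O)C(=O)O"]
    assert (report.catalyzed["gen_iron"] < report.catalyzed["gen_free"]).all()
    row = report.rule_frequencies.loc["Fe+3 Catalyzed Glyceraldehyde to Lactic Acid"]
    assert row["freq_free"] == 0 and row["freq_iron"] == 1
    assert row["percent_change"] == "-"
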