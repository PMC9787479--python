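"""Rule loading/validation and rule application semantics."""

import itertools
from collections import Counter

import pytest

from ironcrn.library import DATA_DIR
from ironcrn.molecules import mol_for, parse_and_canonicalize
from ironcrn.rules import (
    RuleLoadError,
    _apply_to_tuple,
    apply_rule,
    find_embeddings,
    load_rule_library,
    save_rule_library,
)


def sp(smiles):
    return parse_and_canonicalize(smiles)


ALDOL = "[CX3:1](=[O:2])[CX4!H0:3].[CX3:4]=[O:5]>>[C:1](=[O:2])[C:3][C:4][OX2:5]"


def write_rules(tmp_path, entries, name="lib.yaml"):
    import yaml

    path = tmp_path / name
    path.write_text(yaml.safe_dump({"rules": entries}, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# Loading


def test_load_and_round_trip(tmp_path):
    path = write_rules(tmp_path, [{"name": "Aldol", "smarts": ALDOL}])
    lib = load_rule_library(path)
    assert len(lib) == 1 and lib[0].name == "Aldol"
    out = tmp_path / "out.yaml"
    save_rule_library(lib, out)
    again = load_rule_library(out)
    assert again == lib


def test_duplicate_name_rejected(tmp_path):
    path = write_rules(
        tmp_path,
        [{"name": "R", "smarts": ALDOL}, {"name": "R", "smarts": ALDOL}],
    )
    with pytest.raises(RuleLoadError, match="duplicate"):
        load_rule_library(path)


def test_charge_unbalanced_rule_rejected(tmp_path):
    path = write_rules(
        tmp_path, [{"name": "BadRedox", "smarts": "[Fe+3:1]>>[Fe+2:1]"}]
    )
    with pytest.raises(RuleLoadError, match="charge"):
        load_rule_library(path)


def test_invalid_smarts_rejected(tmp_path):
    path = write_rules(tmp_path, [{"name": "Broken", "smarts": "[C:1](>>[C:1]"}])
    with pytest.raises(RuleLoadError):
        load_rule_library(path)


def test_shipped_formose_library_sizes():
    assert len(load_rule_library(DATA_DIR / "formose.yaml")) == 32
    iron = load_rule_library(DATA_DIR / "iron_redox.yaml")
    assert len(iron) == 7
    assert all(r.iron_dependent for r in iron)


# ---------------------------------------------------------------------------
# Matching / embedding enumeration


@pytest.fixture(scope="module")
def cho_rules():
    return {r.name: r for r in load_rule_library(DATA_DIR / "formose.yaml")}


@pytest.fixture(scope="module")
def iron_rules():
    return {r.name: r for r in load_rule_library(DATA_DIR / "iron_redox.yaml")}


def test_aldol_embedding_yields_glyceraldehyde(cho_rules):
    pool = [sp("OCC=O"), sp("C=O")]  # glycolaldehyde + formaldehyde
    embs = find_embeddings(cho_rules["Aldol Condensation"], pool)
    products = {p.canonical_id for e in embs for p in e.products}
    assert sp("OCC(O)C=O").canonical_id in products  # glyceraldehyde


def test_iron_rule_without_fe3_matches_nothing(iron_rules):
    rule = iron_rules["Fe+3 to Fe+2, Aldehyde to acid"]
    pool = [sp("C=O"), sp("O"), sp("[Fe+2]")]
    assert find_embeddings(rule, pool) == []


def test_symmetric_matches_collapse_to_one_embedding(cho_rules):
    # formoin coupling of two formaldehydes: the two automorphic template
    # assignments are one embedding
    rule = cho_rules["Knoevenagel H"]
    embs = find_embeddings(rule, [sp("C=O")])
    assert len(embs) == 1
    assert [p.canonical_id for p in embs[0].products] == [sp("OCC=O").canonical_id]


def test_embeddings_complete_vs_naive_enumeration(cho_rules):
    """On a small pool, find_embeddings equals the all-ordered-tuples
    enumeration quotiented by (reactant multiset, product multiset)."""
    pool = sorted(
        [sp("C=O"), sp("OCC=O"), sp("O"), sp("OCC(O)C=O")],
        key=lambda s: s.canonical_id,
    )
    for rule in (cho_rules["Aldol Condensation"], cho_rules["Canizzaro"],
                 cho_rules["Knoevenagel H"], cho_rules["Retro Aldol"]):
        naive = set()
        for combo in itertools.product(pool, repeat=rule.n_templates):
            if not all(
                mol_for(s).HasSubstructMatch(rule.rxn.GetReactantTemplate(i))
                for i, s in enumerate(combo)
            ):
                continue
            for products in _apply_to_tuple(rule, combo):
                naive.add(
                    (
                        tuple(sorted(s.canonical_id for s in combo)),
                        tuple(p.canonical_id for p in products),
                    )
                )
        embs = find_embeddings(rule, pool)
        got = {
            (
                tuple(sorted(s.canonical_id for s in e.reactants)),
                tuple(p.canonical_id for p in e.products),
            )
            for e in embs
        }
        assert got == naive
        assert len(embs) == len(got)


# ---------------------------------------------------------------------------
# Application / events


def event_multisets(event):
    return Counter(event.reactants), Counter(event.products)


def test_iron_oxidation_of_formaldehyde(iron_rules):
    """Two-electron aldehyde oxidation: HCHO + H2O + 2Fe3+ ->
    formic acid + 2Fe2+ + 2H+."""
    rule = iron_rules["Fe+3 to Fe+2, Aldehyde to acid"]
    pool = [sp("C=O"), sp("O"), sp("[Fe+3]")]
    embs = find_embeddings(rule, pool)
    assert len(embs) == 1
    event = apply_rule(rule, embs[0])
    reacts, prods = event_multisets(event)
    assert reacts == Counter({"[Fe+3]": 2, "C=O": 1, "O": 1})
    assert prods == Counter({"[Fe+2]": 2, "[H+]": 2, "O=CO": 1})
    assert event.iron_flag


def test_catalytic_iron_appears_on_both_sides(tmp_path):
    """Fe3+-catalyzed glyceraldehyde -> lactic acid: the catalyst is in both
    multisets of the event."""
    from ironcrn.fixtures import FIXTURE_DIR

    rule = load_rule_library(FIXTURE_DIR / "iron_shortcut_iron.yaml")[0]
    pool = [sp("OCC(O)C=O"), sp("[Fe+3]")]
    embs = find_embeddings(rule, pool)
    assert len(embs) == 1
    event = apply_rule(rule, embs[0])
    reacts, prods = event_multisets(event)
    assert reacts["[Fe+3]"] == 1 and prods["[Fe+3]"] == 1
    assert prods[sp("CC(O)C(=O)O").canonical_id] == 1  # lactic acid


def test_cannizzaro_produces_methanol_and_formic_acid(cho_rules):
    """Crossed Cannizzaro on formaldehyde + glycolaldehyde gives methanol or
    formic acid from the HCHO partner depending on its redox role."""
    pool = [sp("C=O"), sp("OCC=O"), sp("O")]
    red = find_embeddings(cho_rules["Canizzaro 2, HCHO (reduction)"], pool)
    ox = find_embeddings(cho_rules["Canizzaro 2, HCHO (oxidation)"], pool)
    red_products = {p.canonical_id for e in red for p in e.products}
    ox_products = {p.canonical_id for e in ox for p in e.products}
    assert sp("CO").canonical_id in red_products  # methanol
    assert sp("OC=O").canonical_id in ox_products  # formic acid


def test_every_event_conserves_atoms_and_charge(cho_rules, iron_rules):
    pool = [sp(s) for s in ("C=O", "OCC=O", "OCC(O)C=O", "O", "[Fe+3]",
                            "[Fe+2]", "[H+]", "CC(=O)C(=O)O")]
    for rule in list(cho_rules.values()) + list(iron_rules.values()):
        for emb in find_embeddings(rule, pool):
            lhs, rhs = Counter(), Counter()
            for s in emb.reactants:
                lhs.update(s.formula)
            for s in emb.products:
                rhs.update(s.formula)
            assert lhs == rhs, rule.name
            assert sum(s.net_charge for s in emb.reactants) == sum(
                s.net_charge for s in emb.products
            ), rule.name
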