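"""Toy rule systems with analytically known networks, and a brute-force oracle.

The toys are encoded as ordinary seed/rule files (under ``data/fixtures/``) so
the CLI can run them unchanged, and they use real molecules (formaldehyde,
trioses) so the full canonicalization path is exercised:

``chain_growth``
    formaldehyde extends an aldehyde by one CH2O unit; reachable masses are
    exactly the multiples of 30 AMU within the cap, one species per mass, so
    the saturated network has ``floor(cap/30)`` species in closed form.
``reversible_pair``
    glyceraldehyde <-> dihydroxyacetone under two mutually inverse rules:
    two species, two events, saturation one generation after the back
    reaction is found.
``iron_shortcut``
    glyceraldehyde reaches lactic acid in three iron-free steps but in one
    step with a catalytic Fe3+ rule: lactic acid is catalyzed by design
    (gen_free=3, gen_iron=1).

:func:`brute_force_expand` re-derives the expansion semantics naively — every
generation it tries all reactant tuples from the full cumulative pool against
all rules, with no frontier bookkeeping or match caching — and is the
reference the optimized engine is verified against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional

from .expansion import (
    ConfigError,
    ExpansionConfig,
    ReactionNetwork,
)
from .library import DATA_DIR, ionic_seeds
from .molecules import mol_for, read_seed_file
from .rules import ReactionEvent, _apply_to_tuple, load_rule_library

FIXTURE_DIR = DATA_DIR / "fixtures"

MONOMER_MASS = 30  # formaldehyde, the chain-growth unit

__all__ = ["ToySystem", "make_toy_system", "brute_force_expand", "FIXTURE_DIR"]


@dataclass(frozen=True)
class ToySystem:
    kind: str
    config: ExpansionConfig
    iron_config: Optional[ExpansionConfig]
    expected: dict


def make_toy_system(kind: str, cap: int = 100, max_generations: int = 10) -> ToySystem:
    """Build a toy system's configuration(s) and exact expected results."""
    if kind == "chain_growth":
        if cap < MONOMER_MASS:
            raise ConfigError(
                f"cap {cap} is below the monomer mass {MONOMER_MASS}"
            )
        seeds = read_seed_file(FIXTURE_DIR / "chain_growth.smi")
        rules = load_rule_library(FIXTURE_DIR / "chain_growth.yaml")
        n = cap // MONOMER_MASS
        expected = {
            "species_masses": [MONOMER_MASS * k for k in range(1, n + 1)],
            "n_species": n,
            "n_events": n - 1,
            "saturation_generation": n if n >= 2 else 1,
            "new_species_per_gen": {
                g: (1 if g < n else 0) for g in range(1, min(n, max_generations) + 1)
            },
        }
        return ToySystem(
            kind=kind,
            config=ExpansionConfig(
                seeds=tuple(seeds), rules=tuple(rules),
                max_generations=max_generations, mass_cap=cap,
            ),
            iron_config=None,
            expected=expected,
        )
    if kind == "reversible_pair":
        seeds = read_seed_file(FIXTURE_DIR / "reversible_pair.smi")
        rules = load_rule_library(FIXTURE_DIR / "reversible_pair.yaml")
        expected = {
            "n_species": 2,  # glyceraldehyde + dihydroxyacetone
            "n_events": 2,  # forward and back migration
            "saturation_generation": 3,
        }
        return ToySystem(
            kind=kind,
            config=ExpansionConfig(
                seeds=tuple(seeds), rules=tuple(rules),
                max_generations=max_generations, mass_cap=cap,
            ),
            iron_config=None,
            expected=expected,
        )
    if kind == "iron_shortcut":
        seeds = read_seed_file(FIXTURE_DIR / "iron_shortcut.smi")
        rules = load_rule_library(FIXTURE_DIR / "iron_shortcut.yaml")
        iron_rules = rules + load_rule_library(
            FIXTURE_DIR / "iron_shortcut_iron.yaml"
        )
        iron_seed_list = seeds + ionic_seeds()
        lactic = "CC(O)C(=O)O"
        expected = {
            "catalyzed": lactic,
            "gen_free": 3,
            "gen_iron": 1,
            "n_products": 4,  # glyceraldehyde, DHA, enediol, lactic acid
            "percent_catalysis": 25.0,
        }
        return ToySystem(
            kind=kind,
            config=ExpansionConfig(
                seeds=tuple(seeds), rules=tuple(rules),
                max_generations=max_generations, mass_cap=cap,
            ),
            iron_config=ExpansionConfig(
                seeds=tuple(iron_seed_list), rules=tuple(iron_rules),
                max_generations=max_generations, mass_cap=cap,
            ),
            expected=expected,
        )
    raise ValueError(f"unknown toy system kind {kind!r}")


def brute_force_expand(
    config: ExpansionConfig, species_guard: int = 1000
) -> ReactionNetwork:
    """Exhaustive, unoptimized re-derivation of :func:`~ironcrn.expansion.expand`.

    Every generation, every ordered reactant tuple drawn from the whole
    cumulative pool is tried against every rule; events are deduplicated by
    (rule, reactant multiset, product multiset) and a species' generation is
    the iteration at which it first appears.  Guarded to networks of at most
    ``species_guard`` species.
    """
    species = {}
    first_gen = {}
    for seed in config.seeds:
        species.setdefault(seed.canonical_id, seed)
        first_gen.setdefault(seed.canonical_id, 0)

    events = []
    event_keys = set()
    new_sp = {}
    new_ev = {}
    saturated_at = None
    generations_run = 0

    for g in range(1, config.max_generations + 1):
        pool = sorted(species.values(), key=lambda s: s.canonical_id)
        found_events = []
        found_species = {}
        for rule in sorted(config.rules, key=lambda r: r.name):
            queries = [rule.rxn.GetReactantTemplate(i) for i in range(rule.n_templates)]
            for combo in itertools.product(pool, repeat=rule.n_templates):
                if sum(1 for sp in combo if not sp.is_ubiquitous) > rule.max_molecular_reactants:
                    continue
                if not all(
                    mol_for(sp).HasSubstructMatch(q)
                    for sp, q in zip(combo, queries)
                ):
                    continue
                for products in _apply_to_tuple(rule, combo):
                    if any(p.nominal_mass > config.mass_cap for p in products):
                        continue
                    key = (
                        rule.name,
                        tuple(sorted(s.canonical_id for s in combo)),
                        tuple(s.canonical_id for s in products),
                    )
                    if key in event_keys:
                        continue
                    event_keys.add(key)
                    found_events.append(
                        ReactionEvent(
                            rule_name=rule.name,
                            reactants=key[1],
                            products=key[2],
                            generation=g,
                            iron_flag=rule.iron_dependent,
                        )
                    )
                    for p in products:
                        if p.canonical_id not in species:
                            found_species[p.canonical_id] = p
        for cid, sp in found_species.items():
            species[cid] = sp
            first_gen[cid] = g
        if len(species) > species_guard:
            raise MemoryError(
                f"brute-force oracle guard exceeded: {len(species)} species"
            )
        events.extend(found_events)
        new_sp[g] = sum(1 for s in found_species.values() if not s.is_ubiquitous)
        new_ev[g] = len(found_events)
        generations_run = g
        if not found_species and not found_events:
            saturated_at = g
            break

    return ReactionNetwork(
        config=config,
        species=species,
        first_generation=first_gen,
        events=events,
        new_species_per_gen=new_sp,
        new_events_per_gen=new_ev,
        generations_run=generations_run,
        saturated_at=saturated_at,
    )
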