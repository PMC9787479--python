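"""Generation-wise reaction-network expansion.

Starting from seed species (generation zero), every rule is applied to the
cumulative species pool each iteration; novel events and species found at
iteration ``g`` form generation ``g``.  Because each iteration exhaustively
processes the cumulative pool, an event's generation equals
``max(first_generation of its reactants) + 1``, which makes labels independent
of enumeration order.  Expansion stops at ``max_generations`` or at
saturation — the first generation producing neither a new species nor a new
event (the pool is then a fixed point and no later generation can differ).

A nominal-mass cap (200 AMU by default) gates whole events: if any
product exceeds the cap, the event is discarded entirely.  The expansion is
purely combinatorial — there is no randomness and no kinetics.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .molecules import Species, within_mass_cap
from .rules import ReactionEvent, ReactionRule, apply_rule, iter_embeddings

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionConfig",
    "ReactionNetwork",
    "ConfigError",
    "MemoryGuardError",
    "expand",
    "novel_counts",
    "saturation_generation",
]


class ConfigError(ValueError):
    """The expansion configuration is invalid (e.g. a seed exceeds the cap)."""


class MemoryGuardError(RuntimeError):
    """The species count exceeded the configured hard limit."""


@dataclass(frozen=True)
class ExpansionConfig:
    seeds: Tuple[Species, ...]
    rules: Tuple[ReactionRule, ...]
    max_generations: int
    mass_cap: int = 200
    max_species: int = 1_000_000

    def __post_init__(self):
        object.__setattr__(self, "seeds", tuple(self.seeds))
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.max_generations < 1:
            raise ConfigError("max_generations must be >= 1")
        if self.mass_cap <= 0:
            raise ConfigError("mass cap must be positive")
        for seed in self.seeds:
            if not within_mass_cap(seed, self.mass_cap):
                raise ConfigError(
                    f"seed {seed.canonical_id!r} (mass {seed.nominal_mass}) "
                    f"exceeds the mass cap of {self.mass_cap} AMU"
                )


@dataclass
class ReactionNetwork:
    """Cumulative species table + event list produced by :func:`expand`."""

    config: ExpansionConfig
    species: Dict[str, Species]
    first_generation: Dict[str, int]
    events: List[ReactionEvent]
    new_species_per_gen: Dict[int, int]  # non-ubiquitous ("novel products")
    new_events_per_gen: Dict[int, int]
    generations_run: int
    saturated_at: Optional[int] = None

    # -- counts ------------------------------------------------------------
    @property
    def n_species(self) -> int:
        """All species, ubiquitous ions and water included."""
        return len(self.species)

    @property
    def n_products(self) -> int:
        """Product-diversity count: species that are not ubiquitous."""
        return sum(1 for s in self.species.values() if not s.is_ubiquitous)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def product_counts_by_generation(self) -> pd.Series:
        """Cumulative non-ubiquitous species count at each generation 0..G."""
        per_gen: Dict[int, int] = {g: 0 for g in range(self.generations_run + 1)}
        for cid, sp in self.species.items():
            if not sp.is_ubiquitous:
                per_gen[self.first_generation[cid]] += 1
        counts = pd.Series(per_gen).sort_index().cumsum()
        counts.index.name = "generation"
        return counts

    def event_counts_by_generation(self) -> pd.Series:
        per_gen = {g: 0 for g in range(self.generations_run + 1)}
        for ev in self.events:
            per_gen[ev.generation] += 1
        counts = pd.Series(per_gen).sort_index().cumsum()
        counts.index.name = "generation"
        return counts


def expand(config: ExpansionConfig) -> ReactionNetwork:
    """Run the expansion.  Deterministic given the configuration."""
    species: Dict[str, Species] = {}
    first_gen: Dict[str, int] = {}
    for seed in config.seeds:
        if seed.canonical_id not in species:
            species[seed.canonical_id] = seed
            first_gen[seed.canonical_id] = 0

    rules = sorted(config.rules, key=lambda r: r.name)
    # Per-rule, per-template candidate lists, partitioned into species first
    # seen before the previous generation ("old") and at it ("frontier").
    cand_old: Dict[str, List[List[Species]]] = {
        r.name: [[] for _ in range(r.n_templates)] for r in rules
    }
    cand_frontier: Dict[str, List[List[Species]]] = {
        r.name: [[] for _ in range(r.n_templates)] for r in rules
    }

    def push(new_species: Sequence[Species]) -> None:
        ordered = sorted(new_species, key=lambda s: s.canonical_id)
        for rule in rules:
            fronts = cand_frontier[rule.name]
            for i in range(rule.n_templates):
                fronts[i].extend(
                    sp for sp in ordered if rule.matches_template(sp, i)
                )

    push(list(species.values()))

    events: List[ReactionEvent] = []
    event_keys = set()
    new_sp_per_gen: Dict[int, int] = {}
    new_ev_per_gen: Dict[int, int] = {}
    saturated_at = None
    generations_run = 0

    for g in range(1, config.max_generations + 1):
        t0 = time.monotonic()
        discovered: Dict[str, Species] = {}
        n_new_events = 0
        for rule in rules:
            old = cand_old[rule.name]
            front = cand_frontier[rule.name]
            alldone = [o + f for o, f in zip(old, front)]
            for emb in iter_embeddings(rule, alldone, frontier=front, old=old):
                event = apply_rule(rule, emb, generation=g)
                if event.key in event_keys:
                    continue
                if not all(
                    within_mass_cap(sp, config.mass_cap) for sp in emb.products
                ):
                    continue  # any over-cap product discards the whole event
                event_keys.add(event.key)
                events.append(event)
                n_new_events += 1
                for sp in emb.products:
                    cid = sp.canonical_id
                    if cid not in species and cid not in discovered:
                        discovered[cid] = sp
        n_new_products = 0
        for cid, sp in discovered.items():
            species[cid] = sp
            first_gen[cid] = g
            if not sp.is_ubiquitous:
                n_new_products += 1
        if len(species) > config.max_species:
            raise MemoryGuardError(
                f"species count {len(species)} exceeded the hard limit of "
                f"{config.max_species} at generation {g}; raise max_species "
                "or lower the mass cap / generation count"
            )
        new_sp_per_gen[g] = n_new_products
        new_ev_per_gen[g] = n_new_events
        generations_run = g
        logger.info(
            "generation %d: %d new species, %d new events, "
            "%d species / %d events total (%.2fs)",
            g, len(discovered), n_new_events, len(species), len(events),
            time.monotonic() - t0,
        )
        # advance frontier
        for rule in rules:
            old = cand_old[rule.name]
            front = cand_frontier[rule.name]
            for i in range(rule.n_templates):
                old[i].extend(front[i])
                front[i] = []
            cand_frontier[rule.name] = front
        push(list(discovered.values()))
        if not discovered and n_new_events == 0:
            saturated_at = g
            break

    return ReactionNetwork(
        config=config,
        species=species,
        first_generation=first_gen,
        events=events,
        new_species_per_gen=new_sp_per_gen,
        new_events_per_gen=new_ev_per_gen,
        generations_run=generations_run,
        saturated_at=saturated_at,
    )


def novel_counts(net: ReactionNetwork) -> pd.DataFrame:
    """Per-generation counts of novel products and novel events.

    Novel-product counts exclude the ubiquitous ionic species; the sum of the
    ``new_species`` column plus the number of non-ubiquitous seeds equals the
    network's total product count.
    """
    gens = sorted(net.new_species_per_gen)
    return pd.DataFrame(
        {
            "generation": gens,
            "new_species": [net.new_species_per_gen[g] for g in gens],
            "new_events": [net.new_events_per_gen[g] for g in gens],
        }
    ).set_index("generation")


def saturation_generation(net: ReactionNetwork) -> Optional[int]:
    """First generation at which nothing new arose, or None if not reached."""
    return net.saturated_at
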