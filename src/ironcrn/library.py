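"""Curated experiment presets: seed sets and rule sets for the four networks.

Each preset (formose, pyruvic, glucose_degradation, maillard) comes in an
iron-free and an iron-containing variant.  The iron variant extends the
iron-free one by the four ionic seeds (Fe2+, Fe3+, H+, OH-) and the iron
redox rules — a strict superset, which is the structural backbone of the
iron-free vs. iron-containing comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import yaml

from .molecules import Species, parse_and_canonicalize, read_seed_file
from .rules import ReactionRule, load_rule_library

DATA_DIR = Path(__file__).parent / "data"

#: Ionic species added to every iron-containing seed set.
IONIC_SEED_SMILES = ("[Fe+2]", "[Fe+3]", "[H+]", "[OH-]")

__all__ = [
    "ExperimentPreset",
    "UnknownPresetError",
    "list_presets",
    "get_preset",
    "get_seed_set",
    "get_rule_set",
]


class UnknownPresetError(KeyError):
    """Raised for a preset name outside the registry."""


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    seed_file: Path
    rule_files: Tuple[Path, ...]
    iron_rule_files: Tuple[Path, ...]
    default_generations: int
    default_mass_cap: int


def _registry() -> Dict[str, dict]:
    with open(DATA_DIR / "presets.yaml") as fh:
        return yaml.safe_load(fh)


def list_presets() -> List[str]:
    return sorted(_registry())


def get_preset(name: str) -> ExperimentPreset:
    registry = _registry()
    try:
        entry = registry[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(registry))}"
        ) from None
    return ExperimentPreset(
        name=name,
        seed_file=DATA_DIR / entry["seeds"],
        rule_files=tuple(DATA_DIR / f for f in entry["rules"]),
        iron_rule_files=tuple(DATA_DIR / f for f in entry.get("iron_rules", [])),
        default_generations=int(entry["generations"]),
        default_mass_cap=int(entry.get("mass_cap", 200)),
    )


def ionic_seeds() -> List[Species]:
    return [parse_and_canonicalize(s) for s in IONIC_SEED_SMILES]


def get_seed_set(name: str, with_iron: bool) -> List[Species]:
    """Seed species for a preset; the iron variant appends the ionic seeds."""
    preset = get_preset(name)
    seeds = read_seed_file(preset.seed_file)
    if with_iron:
        seeds.extend(ionic_seeds())
    return seeds


def get_rule_set(name: str, with_iron: bool) -> List[ReactionRule]:
    """Rules for a preset; the iron variant appends the iron redox rules.

    The iron-containing set is asserted to be a strict extension of the
    iron-free set (same rules plus iron-dependent ones).
    """
    preset = get_preset(name)
    rules: List[ReactionRule] = []
    for path in preset.rule_files:
        rules.extend(load_rule_library(path))
    assert not any(r.iron_dependent for r in rules), (
        f"preset {name}: iron-free rule set contains iron-dependent rules"
    )
    if with_iron:
        for path in preset.iron_rule_files:
            extra = load_rule_library(path)
            assert all(r.iron_dependent for r in extra), (
                f"preset {name}: iron rule file contains iron-free rules"
            )
            rules.extend(extra)
    names = [r.name for r in rules]
    assert len(names) == len(set(names)), f"preset {name}: duplicate rule names"
    return rules
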