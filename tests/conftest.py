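"""Shared fixtures: reduced-scale preset runs and toy networks.

Preset pairs are expanded once per session at desk scale — mass cap 100 AMU
for formose/pyruvic (whose seeds fit under it) and 180 AMU for
glucose/maillard (glucose itself weighs 180), at 4/4/3/3 generations — and
shared across the invariant, analytics and acceptance tests.
"""

from __future__ import annotations

import pytest

from ironcrn.expansion import ExpansionConfig, expand
from ironcrn.fixtures import make_toy_system
from ironcrn.library import get_rule_set, get_seed_set, list_presets

#: preset -> (generations, mass cap) used by the desk-scale runs.
REDUCED_SCALE = {
    "formose": (4, 100),
    "pyruvic": (4, 100),
    "glucose_degradation": (3, 180),
    "maillard": (3, 180),
}


def preset_config(name: str, with_iron: bool) -> ExpansionConfig:
    gens, cap = REDUCED_SCALE[name]
    return ExpansionConfig(
        seeds=tuple(get_seed_set(name, with_iron)),
        rules=tuple(get_rule_set(name, with_iron)),
        max_generations=gens,
        mass_cap=cap,
    )


@pytest.fixture(scope="session")
def preset_pairs():
    """{preset: (iron-free network, iron-containing network)} at desk scale."""
    assert set(REDUCED_SCALE) == set(list_presets())
    return {
        name: (expand(preset_config(name, False)), expand(preset_config(name, True)))
        for name in sorted(REDUCED_SCALE)
    }


@pytest.fixture(scope="session")
def chain_toy():
    return make_toy_system("chain_growth", cap=100)


@pytest.fixture(scope="session")
def chain_net(chain_toy):
    return expand(chain_toy.config)


@pytest.fixture(scope="session")
def shortcut_toy():
    return make_toy_system("iron_shortcut")


@pytest.fixture(scope="session")
def shortcut_nets(shortcut_toy):
    return expand(shortcut_toy.config), expand(shortcut_toy.iron_config)
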