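"""Network serialization: CSV tables, JSON manifests, GraphML/GEXF exports.

The on-disk form of a network is a pair of comma-delimited tables —
``nodes.csv`` (one row per species) and ``edges.csv`` (one row per reaction
event) — plus a ``manifest.json`` echoing the configuration and the
per-generation counts.  The tables are loss-free: :func:`load_network`
reconstructs the species set, event list and generation labels exactly.

Graph exports are bipartite directed graphs: species nodes and reaction-event
nodes, with reactant->event and event->product edges (one edge per multiset
slot).  Events from iron-dependent rules carry ``iron_flag`` so viewers can
color iron chemistry separately.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import networkx as nx
import pandas as pd

from .expansion import ExpansionConfig, ReactionNetwork
from .molecules import parse_and_canonicalize
from .rules import ReactionEvent
from .analytics import degree_metrics

__all__ = [
    "write_network",
    "load_network",
    "export_network",
    "network_graph",
    "write_comparison",
]

_SEP = "."  # canonical SMILES of a connected species never contains a dot


def _join(ids) -> str:
    return _SEP.join(ids)


def _split(text: str) -> tuple:
    return tuple(text.split(_SEP)) if text else ()


def nodes_table(net: ReactionNetwork) -> pd.DataFrame:
    degrees = degree_metrics(net)
    rows = []
    for cid in sorted(net.species):
        sp = net.species[cid]
        rows.append(
            {
                "species": cid,
                "formula": "".join(
                    f"{el}{n}" for el, n in sorted(sp.formula.items())
                ),
                "nominal_mass": sp.nominal_mass,
                "net_charge": sp.net_charge,
                "is_ubiquitous": sp.is_ubiquitous,
                "first_generation": net.first_generation[cid],
                "in_degree": degrees.at[cid, "in_degree"],
                "out_degree": degrees.at[cid, "out_degree"],
                "total_degree": degrees.at[cid, "total_degree"],
            }
        )
    return pd.DataFrame(rows)


def edges_table(net: ReactionNetwork) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(net.events):
        rows.append(
            {
                "event_id": i,
                "rule": ev.rule_name,
                "generation": ev.generation,
                "iron_flag": ev.iron_flag,
                "reactants": _join(ev.reactants),
                "products": _join(ev.products),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "rule", "generation", "iron_flag", "reactants", "products",
        ],
    )


def manifest_dict(net: ReactionNetwork) -> dict:
    cfg = net.config
    return {
        "config": {
            "seeds": sorted(s.canonical_id for s in cfg.seeds),
            "rules": sorted(r.name for r in cfg.rules),
            "max_generations": cfg.max_generations,
            "mass_cap": cfg.mass_cap,
        },
        "totals": {
            "species": net.n_species,
            "products": net.n_products,
            "events": net.n_events,
        },
        "new_species_per_generation": {
            str(g): n for g, n in sorted(net.new_species_per_gen.items())
        },
        "new_events_per_generation": {
            str(g): n for g, n in sorted(net.new_events_per_gen.items())
        },
        "generations_run": net.generations_run,
        "saturated_at": net.saturated_at,
    }


def write_network(net: ReactionNetwork, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes_table(net).to_csv(outdir / "nodes.csv", index=False)
    edges_table(net).to_csv(outdir / "edges.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest_dict(net), fh, indent=2)
    return outdir


def load_network(outdir) -> ReactionNetwork:
    """Reconstruct a network from its CSV/manifest directory."""
    outdir = Path(outdir)
    nodes = pd.read_csv(outdir / "nodes.csv")
    edges = pd.read_csv(outdir / "edges.csv")
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)

    species = {}
    first_gen: Dict[str, int] = {}
    for row in nodes.itertuples():
        sp = parse_and_canonicalize(row.species)
        species[sp.canonical_id] = sp
        first_gen[sp.canonical_id] = int(row.first_generation)

    events: List[ReactionEvent] = []
    for row in edges.itertuples():
        events.append(
            ReactionEvent(
                rule_name=row.rule,
                reactants=_split(row.reactants),
                products=_split(row.products),
                generation=int(row.generation),
                iron_flag=bool(row.iron_flag),
            )
        )

    cfg_echo = manifest["config"]
    config = ExpansionConfig(
        seeds=tuple(species[c] for c in cfg_echo["seeds"] if c in species),
        rules=(),
        max_generations=cfg_echo["max_generations"],
        mass_cap=cfg_echo["mass_cap"],
    )
    return ReactionNetwork(
        config=config,
        species=species,
        first_generation=first_gen,
        events=events,
        new_species_per_gen={
            int(g): n for g, n in manifest["new_species_per_generation"].items()
        },
        new_events_per_gen={
            int(g): n for g, n in manifest["new_events_per_generation"].items()
        },
        generations_run=manifest["generations_run"],
        saturated_at=manifest["saturated_at"],
    )


def network_graph(net: ReactionNetwork) -> nx.MultiDiGraph:
    """Bipartite species/reaction-event multigraph of the network."""
    graph = nx.MultiDiGraph()
    for cid in sorted(net.species):
        sp = net.species[cid]
        graph.add_node(
            cid,
            kind="species",
            nominal_mass=sp.nominal_mass,
            net_charge=sp.net_charge,
            is_ubiquitous=sp.is_ubiquitous,
            first_generation=net.first_generation[cid],
        )
    for i, ev in enumerate(net.events):
        node = f"event:{i}"
        graph.add_node(
            node,
            kind="reaction",
            rule=ev.rule_name,
            generation=ev.generation,
            iron_flag=ev.iron_flag,
        )
        for cid in ev.reactants:
            graph.add_edge(cid, node)
        for cid in ev.products:
            graph.add_edge(node, cid)
    return graph


def export_network(net: ReactionNetwork, path, fmt: str = "graphml") -> Path:
    """Export as GraphML or GEXF for Gephi-style visualization."""
    path = Path(path)
    graph = network_graph(net)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "gexf":
        nx.write_gexf(graph, path)
    else:
        raise ValueError(f"unknown export format {fmt!r} (graphml or gexf)")
    return path


def write_comparison(report, outdir) -> Path:
    """Write the comparison report tables (catalysis.csv, degrees.csv,
    rule_frequencies.csv) and a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.catalyzed.to_csv(outdir / "catalysis.csv", index=False)
    merged = report.degrees_free.join(
        report.degrees_iron, how="outer", lsuffix="_free", rsuffix="_iron"
    ).fillna(0).astype(int)
    merged.to_csv(outdir / "degrees.csv")
    report.rule_frequencies.to_csv(outdir / "rule_frequencies.csv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2)
    return outdir
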