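"""Quantitative comparison of an iron-free and an iron-containing network.

The iron-containing variant of a network is a strict structural superset of
its iron-free twin (same rules plus iron rules, same seeds plus ions), so for
every shared species ``gen_iron <= gen_free``.  A compound is *catalyzed* when
the inequality is strict — it is reached in fewer reaction steps once iron
chemistry is available.  Percent catalysis is reported against the iron-free
product count.  The remaining metrics are the standard network summaries:
per-species in/out/total degree (an event contributes its full reactant and
product multiplicities, so a catalyst gains both an in- and an out-edge),
per-rule application frequencies with percent change, and log-linear growth
fits used to extrapolate product counts beyond what is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expansion import ReactionNetwork
from .molecules import Species

__all__ = [
    "ComparisonReport",
    "GrowthFitError",
    "catalyzed_species",
    "percent_catalysis",
    "catalysis_percentage",
    "format_percent",
    "degree_metrics",
    "rule_frequency",
    "frequency_change",
    "growth_fit",
    "compare",
]


class GrowthFitError(ValueError):
    """Growth fitting needs at least two strictly positive counts."""


# ---------------------------------------------------------------------------
# Catalysis


def catalyzed_species(
    free: ReactionNetwork, iron: ReactionNetwork
) -> List[Tuple[Species, int, int]]:
    """Species present in both networks with a strictly earlier iron generation.

    Returns (species, gen_free, gen_iron) triples sorted by canonical id.
    """
    out = []
    for cid, gen_free in free.first_generation.items():
        gen_iron = iron.first_generation.get(cid)
        if gen_iron is not None and gen_iron < gen_free:
            out.append((free.species[cid], gen_free, gen_iron))
    out.sort(key=lambda t: t[0].canonical_id)
    return out


def catalysis_percentage(n_catalyzed: int, n_free_products: int) -> Optional[float]:
    """100 * catalyzed / iron-free product count; None for an empty network."""
    if n_free_products == 0:
        return None
    return 100.0 * n_catalyzed / n_free_products


def percent_catalysis(
    free: ReactionNetwork, iron: ReactionNetwork
) -> Optional[float]:
    return catalysis_percentage(len(catalyzed_species(free, iron)), free.n_products)


def format_percent(value: Optional[float]) -> str:
    """Report precision: one decimal below 2%, nearest integer otherwise."""
    if value is None:
        return "n/a"
    if value < 2.0:
        return f"{value:.1f}%"
    return f"{round(value):d}%"


# ---------------------------------------------------------------------------
# Degrees and rule frequencies


def degree_metrics(net: ReactionNetwork) -> pd.DataFrame:
    """Per-species in/out/total degree, counting event multiplicity.

    out_degree(s) sums s's multiplicity as a reactant over all events,
    in_degree(s) as a product; a catalytic participant appears in both
    multisets of its event and gains both.
    """
    index = sorted(net.species)
    in_deg = {cid: 0 for cid in index}
    out_deg = {cid: 0 for cid in index}
    for ev in net.events:
        for cid in ev.reactants:
            out_deg[cid] += 1
        for cid in ev.products:
            in_deg[cid] += 1
    df = pd.DataFrame(
        {
            "in_degree": [in_deg[c] for c in index],
            "out_degree": [out_deg[c] for c in index],
        },
        index=pd.Index(index, name="species"),
    )
    df["total_degree"] = df["in_degree"] + df["out_degree"]
    return df


def rule_frequency(net: ReactionNetwork) -> pd.Series:
    """Rule name -> number of events; includes zero rows for unapplied rules."""
    counts = {rule.name: 0 for rule in net.config.rules}
    for ev in net.events:
        counts[ev.rule_name] = counts.get(ev.rule_name, 0) + 1
    freq = pd.Series(counts, name="frequency").sort_index()
    freq.index.name = "rule"
    return freq


def frequency_change(f_free: int, f_iron: int) -> Optional[int]:
    """Percent change 100*(f_iron - f_free)/f_free, rounded to integer.

    Returns None (rendered as "-") when the rule never fires without iron.
    """
    if f_free < 0 or f_iron < 0:
        raise ValueError("frequencies must be non-negative")
    if f_free == 0:
        return None
    return round(100.0 * (f_iron - f_free) / f_free)


# ---------------------------------------------------------------------------
# Growth fitting


def growth_fit(
    counts: Sequence[float],
    generations: Optional[Sequence[int]] = None,
    project: Optional[Sequence[int]] = None,
) -> dict:
    """Least-squares line on log10(count) vs generation, with projections.

    ``counts`` are cumulative species (or event) counts per generation.
    Projections back-transform the fitted line at the requested generations;
    they are extrapolations and systematically overestimate once the network
    approaches saturation under its mass cap.
    """
    counts = np.asarray(counts, dtype=float)
    if generations is None:
        generations = np.arange(len(counts))
    generations = np.asarray(generations, dtype=float)
    if counts.size < 2:
        raise GrowthFitError("need at least two data points")
    if np.any(counts <= 0):
        raise GrowthFitError("counts must be strictly positive for a log fit")
    slope, intercept = np.polyfit(generations, np.log10(counts), 1)
    fit = {"log_slope": float(slope), "intercept": float(intercept)}
    if project is not None:
        fit["projections"] = {
            int(g): float(10 ** (slope * g + intercept)) for g in project
        }
    return fit


# ---------------------------------------------------------------------------
# Full report


@dataclass
class ComparisonReport:
    catalyzed: pd.DataFrame  # species, gen_free, gen_iron
    percent_catalysis: Optional[float]
    degrees_free: pd.DataFrame
    degrees_iron: pd.DataFrame
    rule_frequencies: pd.DataFrame  # rule, freq_free, freq_iron, percent_change
    growth_free: dict
    growth_iron: dict

    def summary(self) -> Dict[str, object]:
        return {
            "n_catalyzed": int(len(self.catalyzed)),
            "percent_catalysis": self.percent_catalysis,
            "percent_catalysis_printed": format_percent(self.percent_catalysis),
            "growth_free": self.growth_free,
            "growth_iron": self.growth_iron,
        }


def compare(
    free: ReactionNetwork,
    iron: ReactionNetwork,
    project_generations: Optional[Sequence[int]] = None,
) -> ComparisonReport:
    """Build the full iron-free vs iron-containing comparison report."""
    cat = catalyzed_species(free, iron)
    cat_df = pd.DataFrame(
        {
            "species": [sp.canonical_id for sp, _, _ in cat],
            "gen_free": [gf for _, gf, _ in cat],
            "gen_iron": [gi for _, _, gi in cat],
        }
    )
    freq_free = rule_frequency(free)
    freq_iron = rule_frequency(iron)
    rules = sorted(set(freq_free.index) | set(freq_iron.index))
    rows = []
    for rule in rules:
        f0 = int(freq_free.get(rule, 0))
        f1 = int(freq_iron.get(rule, 0))
        change = frequency_change(f0, f1)
        rows.append(
            {
                "rule": rule,
                "freq_free": f0,
                "freq_iron": f1,
                "percent_change": "-" if change is None else change,
            }
        )
    freq_df = pd.DataFrame(rows).set_index("rule")

    def _fit(net: ReactionNetwork) -> dict:
        counts = net.product_counts_by_generation()
        positive = counts[counts > 0]
        if len(positive) < 2:
            return {}
        last = int(counts.index.max())
        return growth_fit(
            positive.to_numpy(),
            generations=positive.index.to_numpy(),
            project=(range(last + 1, last + 3)
                     if project_generations is None else project_generations),
        )

    return ComparisonReport(
        catalyzed=cat_df,
        percent_catalysis=catalysis_percentage(len(cat), free.n_products),
        degrees_free=degree_metrics(free),
        degrees_iron=degree_metrics(iron),
        rule_frequencies=freq_df,
        growth_free=_fit(free),
        growth_iron=_fit(iron),
    )
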