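"""Reaction mechanisms as graph-transformation rules and their application.

A rule is an L/K/R graph rewrite expressed as an atom-mapped reaction SMARTS:
the left pattern selects subgraphs (bonds to break, wildcard atoms allowed),
the right pattern is the rewritten subgraph (bonds to form, charge changes such
as Fe(III)->Fe(II)).  Subgraph matching and the rewrite itself are delegated to
RDKit's reaction machinery; this module adds the semantics the network
expansion needs on top of it:

* hydrogen renormalization — after a rewrite, hydrogen counts on C/N/O are
  recomputed from valence, so rules only need to state skeleton, bond-order
  and charge edits and hydrogen migration is implicit and exactly balanced;
* a valence guard — applications whose product graphs cannot be sanitized
  (C>4, O>2, N>3 bonds) are silently rejected, as are the rare applications
  that would break atom or charge conservation;
* automorphism deduplication — applications are quotiented by their outcome,
  i.e. two matches related by a pattern symmetry yield one embedding;
* a reactant-count constraint — at most ``max_molecular_reactants`` (default
  2) non-ubiquitous reactants per event; water, H+, OH- and the iron ions may
  participate in any number.

Rule libraries are YAML files (one ``rules:`` list per file, with optional
``include:`` of sibling files); see the shipped files under ``data/``.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from .molecules import Species, mol_for, species_from_mol

__all__ = [
    "ReactionRule",
    "RuleEmbedding",
    "ReactionEvent",
    "RuleError",
    "RuleLoadError",
    "load_rule_library",
    "save_rule_library",
    "find_embeddings",
    "apply_rule",
]


class RuleError(ValueError):
    """Base class for rule-library errors."""


class RuleLoadError(RuleError):
    """A rule file failed to load or a rule failed validation."""


@dataclass(frozen=True)
class ReactionRule:
    """A named L/K/R reaction rule.

    ``smarts`` is an atom-mapped reaction SMARTS; ``iron_dependent`` marks
    mechanisms that require Fe2+/Fe3+ as electron donor/acceptor or catalyst.
    ``provenance`` optionally records the literature-vetting metadata
    (temperature and pH range, citation) used when curating the library.
    """

    name: str
    smarts: str
    iron_dependent: bool = False
    max_molecular_reactants: int = 2
    inverse_of: Optional[str] = None
    provenance: Optional[dict] = field(default=None, compare=False)
    _rxn: object = field(default=None, compare=False, repr=False)
    _queries: tuple = field(default=(), compare=False, repr=False)
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        return self._rxn

    @property
    def n_templates(self) -> int:
        return len(self._queries)

    def matches_template(self, species: Species, index: int) -> bool:
        """Does ``species`` match reactant template ``index``? (cached)"""
        key = (index, species.canonical_id)
        hit = self._cache.get(key)
        if hit is None:
            hit = mol_for(species).HasSubstructMatch(self._queries[index])
            self._cache[key] = hit
        return hit


@dataclass(frozen=True)
class RuleEmbedding:
    """One distinct way of applying a rule to species of a pool.

    Embeddings are represented by their outcome — the reactant multiset
    (ordered per rule template) together with the canonical product multiset —
    which quotients matches related by a pattern automorphism into one
    embedding.
    """

    rule: ReactionRule
    reactants: Tuple[Species, ...]
    products: Tuple[Species, ...]


@dataclass(frozen=True)
class ReactionEvent:
    """One application of a rule: reactant multiset -> product multiset."""

    rule_name: str
    reactants: Tuple[str, ...]  # canonical ids, sorted (multiset)
    products: Tuple[str, ...]  # canonical ids, sorted (multiset)
    generation: int
    iron_flag: bool

    @property
    def key(self) -> tuple:
        return (self.rule_name, self.reactants, self.products)


# ---------------------------------------------------------------------------
# Loading and validation


def _template_charge(template_mols) -> int:
    total = 0
    for mol in template_mols:
        for atom in mol.GetAtoms():
            total += atom.GetFormalCharge()
    return total


def _compile_rule(spec: dict, source: str) -> ReactionRule:
    try:
        name = spec["name"]
        smarts = spec["smarts"]
    except (KeyError, TypeError) as exc:
        raise RuleLoadError(f"{source}: rule entry missing {exc}") from exc
    try:
        rxn = AllChem.ReactionFromSmarts(smarts)
    except Exception as exc:
        raise RuleLoadError(
            f"{source}: rule {name!r}: invalid reaction SMARTS ({exc})"
        ) from exc
    if rxn is None:
        raise RuleLoadError(f"{source}: rule {name!r}: invalid reaction SMARTS")
    rxn.Initialize()
    n_warn, n_err = rxn.Validate(silent=True)
    if n_err:
        raise RuleLoadError(
            f"{source}: rule {name!r}: inconsistent edit set "
            f"({n_err} error(s) validating reaction SMARTS)"
        )
    charge_in = _template_charge(rxn.GetReactants())
    charge_out = _template_charge(rxn.GetProducts())
    if charge_in != charge_out:
        raise RuleLoadError(
            f"{source}: rule {name!r}: net charge changes by "
            f"{charge_out - charge_in} across the rule"
        )
    return ReactionRule(
        name=name,
        smarts=smarts,
        iron_dependent=bool(spec.get("iron_dependent", False)),
        max_molecular_reactants=int(spec.get("max_molecular_reactants", 2)),
        inverse_of=spec.get("inverse_of"),
        provenance=spec.get("provenance"),
        _rxn=rxn,
        _queries=tuple(rxn.GetReactants()),
    )


def load_rule_library(path) -> List[ReactionRule]:
    """Load a YAML rule library (resolving ``include:`` entries).

    Raises :class:`RuleLoadError` on duplicate names, unparsable or
    charge-unbalanced rules.
    """
    path = Path(path)
    if not path.exists():
        raise RuleLoadError(f"rule file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    rules: List[ReactionRule] = []
    for inc in doc.get("include", []) or []:
        rules.extend(load_rule_library(path.parent / inc))
    for spec in doc.get("rules", []) or []:
        rules.append(_compile_rule(spec, str(path)))
    seen: Dict[str, int] = {}
    for rule in rules:
        if rule.name in seen:
            raise RuleLoadError(f"{path}: duplicate rule name {rule.name!r}")
        seen[rule.name] = 1
    return rules


def save_rule_library(rules: Sequence[ReactionRule], path) -> None:
    """Write rules back to a YAML library file (inverse of loading)."""
    entries = []
    for rule in rules:
        entry = {"name": rule.name, "smarts": rule.smarts}
        if rule.iron_dependent:
            entry["iron_dependent"] = True
        if rule.max_molecular_reactants != 2:
            entry["max_molecular_reactants"] = rule.max_molecular_reactants
        if rule.inverse_of:
            entry["inverse_of"] = rule.inverse_of
        if rule.provenance:
            entry["provenance"] = rule.provenance
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump({"rules": entries}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Application


def _normalize_product(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Recompute hydrogens from valence; None if the graph is valence-impossible."""
    try:
        rw = Chem.RWMol(mol)
        for atom in rw.GetAtoms():
            if atom.GetAtomicNum() in (6, 7, 8):
                atom.SetNumExplicitHs(0)
                atom.SetNoImplicit(False)
        Chem.SanitizeMol(rw)
        return rw.GetMol()
    except Exception:
        return None


def _conserves(reactants: Sequence[Species], products: Sequence[Species]) -> bool:
    lhs: Counter = Counter()
    rhs: Counter = Counter()
    for sp in reactants:
        lhs.update(sp.formula)
    for sp in products:
        rhs.update(sp.formula)
    if lhs != rhs:
        return False
    return sum(s.net_charge for s in reactants) == sum(
        s.net_charge for s in products
    )


def _apply_to_tuple(
    rule: ReactionRule, combo: Tuple[Species, ...]
) -> List[Tuple[Species, ...]]:
    """All distinct product multisets from applying ``rule`` to ``combo``."""
    try:
        outcomes = rule.rxn.RunReactants(tuple(mol_for(sp) for sp in combo))
    except Exception:
        return []
    seen = set()
    results: List[Tuple[Species, ...]] = []
    for prods in outcomes:
        species = []
        for mol in prods:
            norm = _normalize_product(mol)
            if norm is None:
                species = None
                break
            try:
                species.append(species_from_mol(norm))
            except Exception:
                species = None
                break
        if species is None:
            continue
        if not _conserves(combo, species):
            # A mis-specified or context-surprised edit; treated as no-match.
            continue
        out = tuple(sorted(species, key=lambda s: s.canonical_id))
        if out not in seen:
            seen.add(out)
            results.append(out)
    return results


def iter_embeddings(
    rule: ReactionRule,
    candidates: Sequence[Sequence[Species]],
    frontier: Optional[Sequence[Sequence[Species]]] = None,
    old: Optional[Sequence[Sequence[Species]]] = None,
) -> Iterable[RuleEmbedding]:
    """Enumerate embeddings given per-template candidate species lists.

    When ``frontier``/``old`` are given (per-template partitions of the
    candidates), only combinations containing at least one frontier species
    are enumerated — each exactly once.  Used by the expansion's
    generation-wise incremental search.
    """
    k = rule.n_templates
    if frontier is None:
        pools = [candidates]
    else:
        assert old is not None
        pools = []
        for j in range(k):
            sel = [old[i] for i in range(j)]
            sel.append(frontier[j])
            sel.extend(candidates[i] for i in range(j + 1, k))
            pools.append(sel)
    seen = set()
    for sel in pools:
        if any(len(lst) == 0 for lst in sel):
            continue
        for combo in itertools.product(*sel):
            n_molecular = sum(1 for sp in combo if not sp.is_ubiquitous)
            if n_molecular > rule.max_molecular_reactants:
                continue
            for products in _apply_to_tuple(rule, combo):
                key = (
                    tuple(sorted(sp.canonical_id for sp in combo)),
                    tuple(sp.canonical_id for sp in products),
                )
                if key in seen:
                    continue
                seen.add(key)
                yield RuleEmbedding(rule=rule, reactants=combo, products=products)


def find_embeddings(
    rule: ReactionRule, pool: Iterable[Species]
) -> List[RuleEmbedding]:
    """All distinct applications of ``rule`` to species of ``pool``.

    Complete up to pattern automorphism: every distinct (reactant multiset,
    product multiset) outcome appears exactly once, enumerated in canonical
    order so runs are reproducible.
    """
    species = sorted(set(pool), key=lambda s: s.canonical_id)
    candidates = [
        [sp for sp in species if rule.matches_template(sp, i)]
        for i in range(rule.n_templates)
    ]
    return list(iter_embeddings(rule, candidates))


def apply_rule(
    rule: ReactionRule, embedding: RuleEmbedding, generation: int = 1
) -> ReactionEvent:
    """Turn an embedding into a :class:`ReactionEvent`.

    Catalytic participants (e.g. Fe3+ mapped unchanged through the rule)
    appear in both the reactant and product multisets.
    """
    if embedding.rule is not rule and embedding.rule != rule:
        raise RuleError("embedding does not belong to this rule")
    return ReactionEvent(
        rule_name=rule.name,
        reactants=tuple(sorted(sp.canonical_id for sp in embedding.reactants)),
        products=tuple(sorted(sp.canonical_id for sp in embedding.products)),
        generation=generation,
        iron_flag=rule.iron_dependent,
    )
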