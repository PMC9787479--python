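"""Canonical representation of molecules and monatomic ions.

Every compound entering a reaction network is reduced to a canonical SMILES
string so that chemically identical products deduplicate regardless of how a
rule application happened to write them.  The model is deliberately minimal:
CHO(+N) organic chemistry plus the aqueous iron ions and water autoionization
products.  Stereochemistry is ignored (no rule in the library is
stereospecific) and tautomers are distinct species connected by explicit
migration rules.

Masses are nominal integer masses (most-abundant isotope), the currency of the
expansion's mass cap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Mapping

from rdkit import Chem, RDLogger

# Rejected rule applications and bare-ion parses are expected; keep RDKit quiet.
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Species",
    "MoleculeError",
    "MalformedInputError",
    "UnsupportedElementError",
    "parse_and_canonicalize",
    "species_from_mol",
    "nominal_mass",
    "within_mass_cap",
    "mol_for",
]

#: Nominal (most-abundant-isotope) integer masses, in AMU.
NOMINAL_MASS: Dict[str, int] = {"H": 1, "C": 12, "N": 14, "O": 16, "Fe": 56}

ALLOWED_ELEMENTS = frozenset(NOMINAL_MASS)


class MoleculeError(ValueError):
    """Base class for molecule-model errors."""


class MalformedInputError(MoleculeError):
    """The line notation could not be parsed into a molecular graph."""


class UnsupportedElementError(MoleculeError):
    """The molecule contains an element outside {C, H, N, O, Fe}."""


@dataclass(frozen=True)
class Species:
    """A canonicalized molecule or monatomic ion.

    Identity (equality, hashing) is carried entirely by ``canonical_id``;
    the remaining fields are derived bookkeeping.
    """

    canonical_id: str
    formula: Mapping[str, int] = field(compare=False)
    nominal_mass: int = field(compare=False)
    net_charge: int = field(compare=False)
    is_ubiquitous: bool = field(compare=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical_id


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - module constants are valid
        raise MalformedInputError(smiles)
    return Chem.MolToSmiles(mol)


#: Species treated as environmentally unlimited co-reactants: water and the
#: ionic species H+/OH-/Fe2+/Fe3+.  They are excluded from product-diversity
#: counts but participate fully in events and degree metrics.
UBIQUITOUS_IDS = frozenset(
    _canonical(s) for s in ("O", "[H+]", "[OH-]", "[Fe+2]", "[Fe+3]")
)

# Cache of RDKit mols keyed by canonical id; mols are immutable once built.
_MOL_CACHE: Dict[str, Chem.Mol] = {}


def mol_for(species: "Species | str") -> Chem.Mol:
    """RDKit molecule for a species (cached)."""
    cid = species if isinstance(species, str) else species.canonical_id
    mol = _MOL_CACHE.get(cid)
    if mol is None:
        mol = Chem.MolFromSmiles(cid)
        if mol is None:
            raise MalformedInputError(f"not a valid canonical id: {cid!r}")
        _MOL_CACHE[cid] = mol
    return mol


def _formula_of(mol: Chem.Mol) -> Dict[str, int]:
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    return {el: n for el, n in counts.items() if n}


def species_from_mol(mol: Chem.Mol) -> Species:
    """Build a :class:`Species` from an already-sanitized RDKit molecule."""
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            raise UnsupportedElementError(
                f"unsupported element {atom.GetSymbol()!r} in "
                f"{Chem.MolToSmiles(mol)!r} (allowed: C, H, N, O, Fe)"
            )
    canonical_id = Chem.MolToSmiles(mol)
    formula = _formula_of(mol)
    mass = sum(NOMINAL_MASS[el] * n for el, n in formula.items())
    return Species(
        canonical_id=canonical_id,
        formula=formula,
        nominal_mass=mass,
        net_charge=Chem.GetFormalCharge(mol),
        is_ubiquitous=canonical_id in UBIQUITOUS_IDS,
    )


def parse_and_canonicalize(notation: str) -> Species:
    """Parse a line-notation (SMILES) string into a canonical :class:`Species`.

    Raises
    ------
    MalformedInputError
        if the notation is not valid SMILES.
    UnsupportedElementError
        if the molecule contains elements outside {C, H, N, O, Fe}.
    """
    text = notation.strip()
    if not text:
        raise MalformedInputError("empty line notation")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MalformedInputError(f"cannot parse line notation: {text!r}")
    return species_from_mol(mol)


def nominal_mass(species: Species) -> int:
    """Nominal integer mass in AMU (H=1, C=12, N=14, O=16, Fe=56)."""
    return species.nominal_mass


def within_mass_cap(species: Species, cap: int) -> bool:
    """True iff the species' nominal mass does not exceed ``cap`` AMU."""
    if cap <= 0:
        raise ValueError(f"mass cap must be positive, got {cap}")
    return species.nominal_mass <= cap


def read_seed_file(path) -> list:
    """Read a seed-species file: one SMILES per line, ``#`` comments allowed."""
    seeds = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                seeds.append(parse_and_canonicalize(line))
    return seeds
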