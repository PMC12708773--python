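"""Chemical structures and molecular formulas.

Parsing and canonicalization are delegated to RDKit; masses are computed from
an embedded constants table (monoisotopic masses of the most abundant isotope
and IUPAC standard atomic weights) so that results do not drift with toolkit
versions.  The canonical deduplication key is the canonical isomeric SMILES of
the parsed molecular graph: two spellings of one structure collapse to one key,
and stereoisomers remain distinct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ATOMIC_MASSES",
    "Molecule",
    "MolecularFormula",
    "StructureParseError",
    "FormulaParseError",
    "parse_structure",
    "parse_formula",
    "monoisotopic_mass",
    "average_molecular_weight",
]

# element -> (monoisotopic mass of most abundant isotope, standard atomic weight), Da.
# Monoisotopic: CODATA/AME2020 leading-isotope masses; standard weights: IUPAC 2021
# (conventional values for interval elements).
ATOMIC_MASSES: dict[str, tuple[float, float]] = {
    "H": (1.00782503207, 1.008),
    "B": (11.0093054, 10.81),
    "C": (12.0, 12.011),
    "N": (14.0030740048, 14.007),
    "O": (15.9949146196, 15.999),
    "F": (18.99840322, 18.998403163),
    "Na": (22.9897692809, 22.98976928),
    "Si": (27.9769265325, 28.085),
    "P": (30.97376163, 30.973761998),
    "S": (31.97207100, 32.06),
    "Cl": (34.96885268, 35.45),
    "K": (38.96370668, 39.0983),
    "Br": (78.9183371, 79.904),
    "Se": (79.9165213, 78.971),
    "I": (126.904473, 126.90447),
}

VALID_LABELS = ("active", "inactive", "unknown")


class StructureParseError(ValueError):
    """Raised when a structure line notation cannot be parsed.

    Carries the offending input so curation can count and log removals.
    """

    def __init__(self, text: str, reason: str = "unparsable structure"):
        self.text = text
        self.reason = reason
        super().__init__(f"{reason}: {text!r}")


class FormulaParseError(ValueError):
    """Raised for malformed molecular formulas; names the offending token."""

    def __init__(self, text: str, token: str, reason: str):
        self.text = text
        self.token = token
        super().__init__(f"{reason} ({token!r}) in formula {text!r}")


@dataclass
class Molecule:
    """One chemical structure with identity, label, and derived properties.

    ``canonical_key`` is derived from the parsed graph (canonical isomeric
    SMILES), never from the input text, so it is identical for any two
    spellings of the same structure.
    """

    id: str
    smiles: str
    canonical_key: str
    label: str = "unknown"
    name: str = ""
    source: str = ""
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def rdkit_mol(self) -> Chem.Mol:
        if self.mol is None:
            self.mol = Chem.MolFromSmiles(self.smiles)
        return self.mol

    def element_counts(self) -> dict[str, int]:
        """Element counts of the structure, implicit hydrogens included."""
        counts: dict[str, int] = {}
        for atom in self.rdkit_mol.GetAtoms():
            counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
            h = atom.GetTotalNumHs()
            if h:
                counts["H"] = counts.get("H", 0) + h
        return counts


class MolecularFormula(dict):
    """Element-symbol → count map with validated symbols and positive counts."""

    def __init__(self, element_counts: Mapping[str, int]):
        if not element_counts:
            raise FormulaParseError("", "", "empty formula: at least one element required")
        for element, count in element_counts.items():
            if element not in ATOMIC_MASSES:
                raise FormulaParseError(str(dict(element_counts)), element, "unknown element")
            if not isinstance(count, int) or count < 1:
                raise FormulaParseError(
                    str(dict(element_counts)), f"{element}{count}", "count must be a positive integer"
                )
        super().__init__(element_counts)


def parse_structure(
    text: str,
    *,
    id: str = "",
    name: str = "",
    label: str = "unknown",
    source: str = "",
) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` with a canonical key.

    Raises :class:`StructureParseError` on unparsable input; never returns a
    partial structure.
    """
    if not text or not text.strip():
        raise StructureParseError(text, "empty structure text")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureParseError(text)
    key = Chem.MolToSmiles(mol)  # canonical, isomeric: stereo layers retained
    return Molecule(id=id or key, smiles=text.strip(), canonical_key=key,
                    label=label, name=name, source=source, mol=mol)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C7H6O5"``.

    An omitted count means 1; repeated element symbols accumulate. Unknown
    element symbols and explicit zero counts raise :class:`FormulaParseError`.
    """
    if not text or not text.strip():
        raise FormulaParseError(text, "", "empty formula")
    stripped = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(stripped):
        m = _FORMULA_TOKEN.match(stripped, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaParseError(text, stripped[pos:], "invalid token")
        element, digits = m.group(1), m.group(2)
        if element not in ATOMIC_MASSES:
            raise FormulaParseError(text, element, "unknown element")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaParseError(text, f"{element}0", "zero count")
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return MolecularFormula(counts)


def _counts_of(formula_or_molecule) -> Mapping[str, int]:
    if isinstance(formula_or_molecule, Molecule):
        return MolecularFormula(formula_or_molecule.element_counts())
    if isinstance(formula_or_molecule, MolecularFormula):
        return formula_or_molecule
    return MolecularFormula(formula_or_molecule)


def monoisotopic_mass(formula) -> float:
    """Monoisotopic mass in Da: Σ count × most-abundant-isotope mass."""
    counts = _counts_of(formula)
    return sum(ATOMIC_MASSES[e][0] * c for e, c in counts.items())


def average_molecular_weight(formula_or_molecule) -> float:
    """Average molecular weight in Da: Σ count × standard atomic weight.

    Accepts a :class:`MolecularFormula`, a plain element-count mapping, or a
    parsed :class:`Molecule`. This is the mass used by the screening
    applicability-domain window (200–700 Da).
    """
    counts = _counts_of(formula_or_molecule)
    return sum(ATOMIC_MASSES[e][1] * c for e, c in counts.items())
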