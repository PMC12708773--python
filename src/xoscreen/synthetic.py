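"""Seeded synthetic molecular libraries with an implanted activity rule.

The generator assembles valid structures from fixed internal fragment
vocabularies: polyphenol-flavoured scaffolds (benzene, phenol, catechol,
chromone, flavone, pyranose cores) with three substitution slots, filled from
a vocabulary of small substituents.  A molecule is active exactly when one of
its slots carries the designated "pharmacophore" substituent, a galloyl ester
group; labels are then flipped independently with a configurable noise
probability.  This makes every pipeline stage testable without external data:
the activity rule is recoverable from fingerprints, the class balance is
controlled (default 45% active, matching a mildly imbalanced inhibitor
library), and scaffold-vocabulary size controls pairwise-similarity spread.

The rule is deliberately not a model of true xanthine oxidase
structure–activity relationships; it exists so that recovery, null-signal,
and applicability-domain behaviour can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .structures import Molecule, StructureParseError, average_molecular_weight, parse_structure

__all__ = ["SyntheticConfig", "generate_library", "generate_screening_set",
           "PHARMACOPHORE", "SCAFFOLDS", "SUBSTITUENTS"]

#: Galloyl ester substituent whose presence defines activity.  Ring-closure
#: digit 9 cannot collide with the scaffolds' digits when nested in a branch.
PHARMACOPHORE = "OC(=O)c9cc(O)c(O)c(O)c9"

#: Scaffold templates with three substitution slots, roughly ordered from
#: mutually similar (benzenoid) to structurally distinct cores.
SCAFFOLDS: tuple[str, ...] = (
    "c1c({0})cc({1})cc1{2}",                          # benzene
    "c1c({0})cc({1})c(O)c1{2}",                       # phenol
    "c1c({0})c(O)c(O)c({1})c1{2}",                    # catechol
    "O=c1cc({0})oc2c({1})cc({2})cc12",                # chromone
    "O=c1c({0})c(-c2ccc(O)cc2)oc2c({1})cc({2})cc12",  # flavone
    "C1OC(CO)C({0})C({1})C1{2}",                      # pyranose-like
    "c1c({0})cc2ccc({1})cc2c1{2}",                    # naphthalene
    "C({0})C1CCC({1})CC1{2}",                         # cyclohexane
    "c1c({0})nc({1})cc1{2}",                          # pyridine
    "O=C(OC)c1c({0})cc({1})cc1{2}",                   # benzoate ester
)

#: Substituent vocabulary (the pharmacophore is drawn separately).
SUBSTITUENTS: tuple[str, ...] = (
    "O", "OC", "C", "CC", "CCC", "CO", "C(=O)O", "OC(C)=O", "N", "OCC",
    "Cl", "F", "C(C)C", "C=O",
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_molecules: int
    active_fraction: float = 0.45
    label_noise: float = 0.0
    scaffold_vocab_size: int = 8
    substituent_vocab_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 10:
            raise ValueError("n_molecules must be >= 10")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must lie in [0, 1]")
        if not 0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")
        if not 2 <= self.scaffold_vocab_size <= len(SCAFFOLDS):
            raise ValueError(f"scaffold_vocab_size must be in [2, {len(SCAFFOLDS)}]")
        if not 2 <= self.substituent_vocab_size <= len(SUBSTITUENTS):
            raise ValueError(f"substituent_vocab_size must be in [2, {len(SUBSTITUENTS)}]")


_PHARM_QUERY: Chem.Mol | None = None


def _pharm_query() -> Chem.Mol:
    global _PHARM_QUERY
    if _PHARM_QUERY is None:
        _PHARM_QUERY = Chem.MolFromSmiles(PHARMACOPHORE)
    return _PHARM_QUERY


def _assemble(rng: np.random.Generator, scaffolds: Sequence[str],
              subs: Sequence[str], active: bool) -> str:
    scaffold = scaffolds[rng.integers(len(scaffolds))]
    slots = [subs[rng.integers(len(subs))] for _ in range(3)]
    if active:
        slots[rng.integers(3)] = PHARMACOPHORE
    return scaffold.format(*slots)


def generate_library(config: SyntheticConfig) -> list[Molecule]:
    """Generate a deterministic labeled library of unique valid structures.

    Exactly round(active_fraction·n) molecules satisfy the structural rule
    before label noise; structures are unique on the canonical key, so noisy
    labels can never conflict on duplicates downstream.
    """
    rng = np.random.default_rng(config.seed)
    scaffolds = SCAFFOLDS[: config.scaffold_vocab_size]
    subs = SUBSTITUENTS[: config.substituent_vocab_size]
    n_active = round(config.active_fraction * config.n_molecules)
    rule_active = np.zeros(config.n_molecules, dtype=bool)
    rule_active[:n_active] = True
    rng.shuffle(rule_active)

    capacity = config.scaffold_vocab_size * 3 * len(subs) ** 2
    if n_active > 0.9 * capacity:
        raise ValueError(
            f"infeasible config: {n_active} unique actives requested but the "
            f"fragment vocabularies support only ~{capacity}"
        )

    library: list[Molecule] = []
    seen: set[str] = set()
    max_attempts = 200 * config.n_molecules
    attempts = 0
    for i, is_active in enumerate(rule_active):
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "infeasible config: could not assemble enough unique "
                    "structures; enlarge the fragment vocabularies"
                )
            smiles = _assemble(rng, scaffolds, subs, bool(is_active))
            try:
                mol = parse_structure(smiles, id=f"SYN-{i:04d}", source="synthetic")
            except StructureParseError:  # pragma: no cover - vocab is pre-validated
                continue
            if mol.canonical_key in seen:
                continue
            # a random substituent combination may recreate the galloyl-ester
            # pattern by chance; reject it so inactives never satisfy the rule
            if not is_active and mol.rdkit_mol.HasSubstructMatch(_pharm_query()):
                continue
            seen.add(mol.canonical_key)
            break
        label = bool(is_active)
        if config.label_noise and rng.random() < config.label_noise:
            label = not label
        mol.label = "active" if label else "inactive"
        library.append(mol)
    return library


# fixed pools for the planted-outcome screening strata
_MW_FAIL_POOL: tuple[str, ...] = (
    "CCO", "CC(=O)O", "Oc1ccccc1", "CC(C)=O", "OCC(O)CO", "c1ccncc1",
    "C" * 50, "C" * 55, "C" * 60,
)
_EXOTIC_POOL: tuple[str, ...] = (
    "C" * 18, "C" * 20, "CCCCCCCCCCCCCCCC(C)C",
    "FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
    "C1CCCCC1C1CCCCC1C1CCCCC1",
    "CCCCCCCCCCCCCCCCCC(=O)OCC",
)


def generate_screening_set(
    config: SyntheticConfig,
    train_library: Sequence[Molecule],
    n_per_stratum: int = 6,
) -> list[Molecule]:
    """Unlabeled screening candidates in three strata with planted AD outcomes.

    Strata (recorded in each Molecule's ``source``):

    - ``in_vocab``: copies of training structures whose molecular weight lies
      inside the 200–700 Da window — they must pass both AD criteria;
    - ``mw_fail``: deliberately small (< 200 Da) or large (> 700 Da)
      structures — they must fail the molecular-weight criterion;
    - ``exotic``: out-of-vocabulary aliphatic/fluorinated structures of
      in-window weight — they should fail the similarity criterion.
    """
    rng = np.random.default_rng(config.seed + 1)
    in_window = [m for m in train_library
                 if 200 <= average_molecular_weight(m) <= 700]
    if not in_window:
        raise ValueError("training library has no compounds inside the MW window")
    idx = rng.choice(len(in_window), size=min(n_per_stratum, len(in_window)),
                     replace=False)
    candidates: list[Molecule] = []
    for j, i in enumerate(sorted(idx)):
        candidates.append(parse_structure(in_window[i].smiles,
                                          id=f"SCR-IV-{j:03d}", source="in_vocab"))
    for j, smiles in enumerate(_MW_FAIL_POOL[:n_per_stratum]):
        candidates.append(parse_structure(smiles, id=f"SCR-MW-{j:03d}",
                                          source="mw_fail"))
    for j, smiles in enumerate(_EXOTIC_POOL[:n_per_stratum]):
        candidates.append(parse_structure(smiles, id=f"SCR-EX-{j:03d}",
                                          source="exotic"))
    return candidates
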