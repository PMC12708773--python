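"""Library curation and stratified train/validation/test splitting.

Curation collapses duplicate structures on the canonical key (first occurrence
wins), removes records that cannot be parsed or encoded, and accounts for every
removal.  The split is a two-stage stratified draw: a test partition of
ceil(0.15·n) records is removed first, then a validation partition of the same
size from the remainder; per-class quotas come from largest-remainder
apportionment of the global class proportions, so every partition's class
balance is within one compound of the library's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structures import Molecule, StructureParseError, parse_structure

__all__ = [
    "CurationReport",
    "SplitAssignment",
    "curate",
    "stratified_split",
    "library_to_frame",
    "read_library_csv",
]


@dataclass
class CurationReport:
    n_input: int
    n_duplicates_removed: int
    n_encoding_failures: int
    n_retained: int
    removals: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __post_init__(self):
        assert self.n_retained == self.n_input - self.n_duplicates_removed - self.n_encoding_failures


def curate(records: pd.DataFrame | Sequence[Mapping]) -> tuple[list[Molecule], CurationReport]:
    """Curate a labeled structure table into a deduplicated Molecule library.

    ``records`` needs columns/keys ``id`` and ``smiles``; ``label`` defaults to
    ``"unknown"`` and ``name``/``source`` are carried through when present.
    Duplicate structures (same canonical key) collapse to the first occurrence;
    duplicates with conflicting labels raise, listing the offending ids.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    if records.empty:
        raise ValueError("curate: empty input table")
    for col in ("id", "smiles"):
        if col not in records.columns:
            raise ValueError(f"curate: missing required column {col!r}")

    library: list[Molecule] = []
    seen: dict[str, Molecule] = {}
    conflicts: list[tuple[str, str]] = []
    removals: list[tuple[str, str]] = []
    n_dup = n_fail = 0
    for row in records.itertuples(index=False):
        rid = str(row.id)
        label = str(getattr(row, "label", "unknown") or "unknown")
        name = str(getattr(row, "name", "") or "")
        source = str(getattr(row, "source", "") or "")
        try:
            mol = parse_structure(str(row.smiles), id=rid, name=name, label=label, source=source)
        except StructureParseError as err:
            n_fail += 1
            removals.append((rid, f"encoding failure: {err.reason}"))
            continue
        kept = seen.get(mol.canonical_key)
        if kept is not None:
            n_dup += 1
            removals.append((rid, f"duplicate of {kept.id}"))
            if kept.label != mol.label:
                conflicts.append((kept.id, rid))
            continue
        seen[mol.canonical_key] = mol
        library.append(mol)
    if conflicts:
        raise ValueError(
            "conflicting labels on duplicate structures: "
            + ", ".join(f"{a}/{b}" for a, b in conflicts)
        )
    report = CurationReport(
        n_input=len(records),
        n_duplicates_removed=n_dup,
        n_encoding_failures=n_fail,
        n_retained=len(library),
        removals=removals,
    )
    return library, report


@dataclass
class SplitAssignment:
    """Partition of a curated library into train/validation/test id lists."""

    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str]
    seed: int
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratified: bool = True

    def partition_of(self) -> dict[str, str]:
        out = {i: "train" for i in self.train_ids}
        out.update({i: "validation" for i in self.validation_ids})
        out.update({i: "test" for i in self.test_ids})
        return out

    def subset(self, library: Sequence[Molecule], partition: str) -> list[Molecule]:
        ids = {"train": self.train_ids, "validation": self.validation_ids,
               "test": self.test_ids}[partition]
        wanted = set(ids)
        return [m for m in library if m.id in wanted]

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, p) for i, p in self.partition_of().items()]
        return pd.DataFrame(rows, columns=["id", "partition"])


def _largest_remainder(quota: float, counts: Mapping[str, int], size: int) -> dict[str, int]:
    """Apportion `size` draws across classes proportional to `counts`."""
    total = sum(counts.values())
    raw = {c: size * k / total for c, k in counts.items()}
    alloc = {c: math.floor(v) for c, v in raw.items()}
    short = size - sum(alloc.values())
    order = sorted(counts, key=lambda c: (raw[c] - alloc[c], c), reverse=True)
    for c in order[:short]:
        alloc[c] += 1
    return alloc


def stratified_split(
    library: Sequence[Molecule],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified 70/15/15 split with held-out partitions of ceil(0.15·n).

    Deterministic for a fixed seed.  Both held-out draws are stratified by
    label against the global class proportions; e.g. 483 compounds yield
    partitions of 337/73/73.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(library)
    labels = [m.label for m in library]
    classes = sorted(set(labels))
    counts = {c: labels.count(c) for c in classes}
    if len(classes) < 2:
        raise ValueError("stratified split requires at least 2 classes")
    if min(counts.values()) < 3:
        raise ValueError(f"class too small to stratify: {counts}")

    holdout = math.ceil(fractions[2] * n)
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {c: [] for c in classes}
    for m in library:
        by_class[m.label].append(m.id)

    def draw(partition_size: int) -> list[str]:
        alloc = _largest_remainder(partition_size / n, counts, partition_size)
        chosen: list[str] = []
        for c in classes:
            pool = by_class[c]
            if alloc[c] > len(pool):
                raise ValueError(f"class {c!r} exhausted while stratifying")
            idx = rng.choice(len(pool), size=alloc[c], replace=False)
            picked = [pool[i] for i in sorted(idx)]
            chosen.extend(picked)
            by_class[c] = [x for x in pool if x not in set(picked)]
        return chosen

    test_ids = draw(holdout)
    validation_ids = draw(holdout)
    train_ids = [i for ids in by_class.values() for i in ids]
    # restore library order for the train partition
    order = {m.id: k for k, m in enumerate(library)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    validation_ids.sort(key=order.__getitem__)
    return SplitAssignment(train_ids=train_ids, validation_ids=validation_ids,
                           test_ids=test_ids, seed=seed, fractions=fractions)


def library_to_frame(library: Sequence[Molecule]) -> pd.DataFrame:
    """Normalized library table with the appended canonical_key column."""
    return pd.DataFrame(
        {
            "id": [m.id for m in library],
            "name": [m.name for m in library],
            "smiles": [m.smiles for m in library],
            "canonical_key": [m.canonical_key for m in library],
            "label": [m.label for m in library],
            "source": [m.source for m in library],
        }
    )


def read_library_csv(path) -> pd.DataFrame:
    """Read a delimited library file with id, smiles[, label, name] columns."""
    frame = pd.read_csv(path, comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame
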