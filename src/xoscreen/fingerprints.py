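"""Molecular fingerprints, Tanimoto similarity, and library diversity profiles.

Five encoding schemes are supported: the fixed 167-key MACCS dictionary and
extended-connectivity fingerprints of diameter 4 or 6 (radius 2 or 3) folded
to 1024 or 2048 presence bits.  Encoding delegates to RDKit; similarity and
the pairwise diversity profile are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit.Chem import DataStructs, rdFingerprintGenerator, rdMolDescriptors

from .structures import Molecule, StructureParseError

__all__ = [
    "FingerprintScheme",
    "Fingerprint",
    "SCHEMES",
    "encode",
    "encode_matrix",
    "tanimoto",
    "diversity_profile",
    "DiversityProfile",
]

_FAMILIES = {"MACCS": (167,), "ECFP4": (1024, 2048), "ECFP6": (1024, 2048)}
_RADIUS = {"ECFP4": 2, "ECFP6": 3}


@dataclass(frozen=True)
class FingerprintScheme:
    """One of the five legal (family, n_bits) fingerprint configurations."""

    family: str
    n_bits: int

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown fingerprint family {self.family!r}")
        if self.n_bits not in _FAMILIES[self.family]:
            raise ValueError(
                f"{self.family} does not support {self.n_bits} bits "
                f"(legal: {_FAMILIES[self.family]})"
            )

    def __str__(self) -> str:
        return f"{self.family}-{self.n_bits}"

    @classmethod
    def from_string(cls, text: str) -> "FingerprintScheme":
        family, _, bits = text.partition("-")
        return cls(family, int(bits))


#: The five schemes, in reporting order.
SCHEMES: tuple[FingerprintScheme, ...] = (
    FingerprintScheme("MACCS", 167),
    FingerprintScheme("ECFP4", 1024),
    FingerprintScheme("ECFP4", 2048),
    FingerprintScheme("ECFP6", 1024),
    FingerprintScheme("ECFP6", 2048),
)


@dataclass(frozen=True)
class Fingerprint:
    scheme: FingerprintScheme
    bits: np.ndarray  # uint8 0/1 vector of length scheme.n_bits

    def __post_init__(self):
        if self.bits.shape != (self.scheme.n_bits,):
            raise ValueError(
                f"bit vector length {self.bits.shape} does not match scheme {self.scheme}"
            )

    def popcount(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())


_GENERATORS: dict[FingerprintScheme, object] = {}


def _generator(scheme: FingerprintScheme):
    if scheme not in _GENERATORS:
        _GENERATORS[scheme] = rdFingerprintGenerator.GetMorganGenerator(
            radius=_RADIUS[scheme.family], fpSize=scheme.n_bits
        )
    return _GENERATORS[scheme]


def encode(mol: Molecule, scheme: FingerprintScheme) -> Fingerprint:
    """Encode a molecule under a scheme; deterministic for a given structure."""
    rdmol = mol.rdkit_mol
    if rdmol is None:
        raise StructureParseError(mol.smiles, "cannot encode unparsed structure")
    if scheme.family == "MACCS":
        bv = rdMolDescriptors.GetMACCSKeysFingerprint(rdmol)
    else:
        bv = _generator(scheme).GetFingerprint(rdmol)
    arr = np.zeros(scheme.n_bits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(bv, arr)
    return Fingerprint(scheme=scheme, bits=arr)


def encode_matrix(molecules: Sequence[Molecule], scheme: FingerprintScheme) -> np.ndarray:
    """Stack fingerprints of a library into an (n, n_bits) uint8 matrix."""
    return np.vstack([encode(m, scheme).bits for m in molecules])


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between two same-scheme fingerprints.

    Defined as 1.0 (with a warning) when both vectors are all-zero: identical
    absence of features.
    """
    if a.scheme != b.scheme:
        raise ValueError(f"scheme mismatch: {a.scheme} vs {b.scheme}")
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 1.0", stacklevel=2)
        return 1.0
    return inter / union


@dataclass
class DiversityProfile:
    scheme: FingerprintScheme
    threshold: float
    n_pairs: int
    fraction_below: float
    histogram: np.ndarray      # counts per bin
    bin_edges: np.ndarray      # len(histogram) + 1 edges covering [0, 1]

    def plot(self, ax=None):
        """Bar plot of the pairwise-Tc histogram (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        widths = np.diff(self.bin_edges)
        ax.bar(self.bin_edges[:-1], self.histogram, width=widths, align="edge",
               edgecolor="white")
        ax.axvline(self.threshold, color="crimson", linestyle="--",
                   label=f"Tc = {self.threshold}")
        ax.set_xlabel("pairwise Tanimoto coefficient")
        ax.set_ylabel("compound pairs")
        ax.set_title(f"{self.scheme}: {100 * self.fraction_below:.1f}% of pairs "
                     f"below Tc {self.threshold}")
        ax.legend()
        return ax


def diversity_profile(
    library: Sequence[Molecule],
    scheme: FingerprintScheme,
    threshold: float = 0.4,
    n_bins: int = 20,
) -> DiversityProfile:
    """Pairwise-Tc diversity profile over all n(n−1)/2 unordered distinct pairs.

    A high share of pairs below the threshold indicates a structurally diverse
    library; self-pairs are excluded so they cannot inflate the high-Tc mass.
    """
    n = len(library)
    if n < 2:
        raise ValueError("diversity profile requires at least 2 molecules")
    X = encode_matrix(library, scheme).astype(np.int32)
    pop = X.sum(axis=1)
    inter = X @ X.T
    union = pop[:, None] + pop[None, :] - inter
    iu = np.triu_indices(n, k=1)
    inter_p, union_p = inter[iu], union[iu]
    with np.errstate(invalid="ignore"):
        tc = np.where(union_p == 0, 1.0, inter_p / np.maximum(union_p, 1))
    n_pairs = n * (n - 1) // 2
    hist, edges = np.histogram(tc, bins=n_bins, range=(0.0, 1.0))
    # Tc == 1.0 falls in the last bin by numpy's closed right edge; keep as is.
    return DiversityProfile(
        scheme=scheme,
        threshold=threshold,
        n_pairs=n_pairs,
        fraction_below=float(np.mean(tc < threshold)),
        histogram=hist,
        bin_edges=edges,
    )
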