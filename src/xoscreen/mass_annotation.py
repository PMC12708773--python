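"""Negative-mode adduct m/z arithmetic and ppm-error annotation.

Theoretical ion m/z values are computed from molecular formulas by
hydrogen-atom arithmetic: m/z = (k·M + Σ signed monoisotopic masses of the
adduct atoms) / |z|, with the electron mass ignored.  This convention
reproduces published three-decimal values for the supported negative-mode
adducts; proton-mass arithmetic (electron-corrected) is available behind a
flag for comparison.

ppm error is the standard high-resolution MS accuracy measure,
(measured − theoretical)/theoretical × 1e6, reported to two decimals;
deviations below 0.005 ppm display as 0.00.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .structures import ATOMIC_MASSES, MolecularFormula, monoisotopic_mass, parse_formula

__all__ = [
    "AdductSpec",
    "ADDUCTS",
    "AnnotationRow",
    "adduct_mz",
    "ppm_error",
    "annotate_table",
    "load_metabolite_table",
    "ELECTRON_MASS",
]

ELECTRON_MASS = 0.000548579909  # Da


@dataclass(frozen=True)
class AdductSpec:
    """A negative-mode adduct: m/z = (multiplier·M + delta) / |charge|."""

    name: str
    multiplier: int            # count of M in the ion
    delta: tuple[tuple[str, int], ...]  # signed element-count changes
    charge: int = -1

    def __post_init__(self):
        if self.multiplier < 1:
            raise ValueError("adduct multiplier must be >= 1")


#: Built-in adducts; the table is user-extensible by passing extra specs to
#: :func:`annotate_table`.
ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", 1, (("H", -1),)),
    "[M+Cl]-": AdductSpec("[M+Cl]-", 1, (("Cl", 1),)),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", 1, (("C", 1), ("H", 1), ("O", 2))),
    "[2M+Na-2H]-": AdductSpec("[2M+Na-2H]-", 2, (("Na", 1), ("H", -2))),
}


def normalize_adduct_name(text: str) -> str:
    """Map typographic variants ("[M−H]−", "[2 M+Na−2H]^−^") to the ASCII key."""
    t = unicodedata.normalize("NFKC", text)
    t = t.replace("−", "-").replace("–", "-").replace(" ", "")
    t = re.sub(r"\^-?\^?", "", t)
    if t.endswith("]"):
        t += "-"
    return t


def adduct_mz(formula: MolecularFormula | str, adduct: AdductSpec | str,
              electron_corrected: bool = False) -> float:
    """Theoretical ion m/z for a formula under a negative-mode adduct.

    Raises if the adduct would remove more atoms of an element than the
    (multiplied) neutral formula contains.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if isinstance(adduct, str):
        key = normalize_adduct_name(adduct)
        if key not in ADDUCTS:
            raise ValueError(f"unknown or unsupported adduct {adduct!r}")
        adduct = ADDUCTS[key]
    for element, change in adduct.delta:
        if change < 0:
            present = adduct.multiplier * formula.get(element, 0)
            if present + change < 0:
                raise ValueError(
                    f"adduct {adduct.name} removes {-change} {element} but the "
                    f"ion contains only {present}"
                )
    mass = adduct.multiplier * monoisotopic_mass(formula)
    mass += sum(ATOMIC_MASSES[e][0] * c for e, c in adduct.delta)
    if electron_corrected:
        mass -= adduct.charge * ELECTRON_MASS  # negative charge adds electrons
    return mass / abs(adduct.charge)


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


@dataclass
class AnnotationRow:
    name: str
    formula: MolecularFormula
    adduct: AdductSpec
    measured_mz: float
    theoretical_mz: float
    ppm_error: float

    @property
    def ppm_display(self) -> str:
        """Two-decimal display; |Δppm| < 0.005 rounds to 0.00."""
        return f"{self.ppm_error:.2f}"


def annotate_table(
    rows: pd.DataFrame,
    extra_adducts: Mapping[str, AdductSpec] | None = None,
    electron_corrected: bool = False,
) -> tuple[list[AnnotationRow], dict]:
    """Fill theoretical m/z and ppm error for a metabolite annotation table.

    ``rows`` needs columns name, formula, adduct, measured_mz.  Output
    preserves input order; the summary counts rows with |Δppm| ≤ 5, the
    conventional high-resolution identification window.
    """
    adducts = dict(ADDUCTS)
    if extra_adducts:
        adducts.update(extra_adducts)
    out: list[AnnotationRow] = []
    for i, row in rows.reset_index(drop=True).iterrows():
        key = normalize_adduct_name(str(row["adduct"]))
        if key not in adducts:
            raise ValueError(f"row {i} ({row['name']!r}): unknown adduct {row['adduct']!r}")
        spec = adducts[key]
        formula = parse_formula(str(row["formula"]))
        theo = adduct_mz(formula, spec, electron_corrected=electron_corrected)
        out.append(AnnotationRow(
            name=str(row["name"]), formula=formula, adduct=spec,
            measured_mz=float(row["measured_mz"]), theoretical_mz=theo,
            ppm_error=ppm_error(float(row["measured_mz"]), theo),
        ))
    summary = {
        "n_rows": len(out),
        "n_within_5ppm": sum(abs(r.ppm_error) <= 5 for r in out),
    }
    return out, summary


def annotation_to_frame(rows: Sequence[AnnotationRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "name": [r.name for r in rows],
        "adduct": [r.adduct.name for r in rows],
        "measured_mz": [r.measured_mz for r in rows],
        "theoretical_mz": [round(r.theoretical_mz, 6) for r in rows],
        "ppm_error": [float(r.ppm_display) for r in rows],
    })


def load_metabolite_table(which: str) -> pd.DataFrame:
    """Load a bundled annotated-metabolite table.

    ``which`` is ``"bs"`` (the *B. subcupularis* ethyl acetate extract, 23
    compounds) or ``"bt"`` (*B. tobiracola*, 21 compounds).
    """
    if which not in ("bs", "bt"):
        raise ValueError("which must be 'bs' or 'bt'")
    ref = resources.files("xoscreen.data") / f"metabolites_{which}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")
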