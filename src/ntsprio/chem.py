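"""Molecular-formula parsing and monoisotopic mass / adduct m/z arithmetic.

Every downstream stage (suspect screening, quantification, validation)
relies on this module for exact-mass computation. Masses are built from a
pinned principal-isotope table so results are bit-stable across platforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Mapping

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "MolecularFormula",
    "Adduct",
    "ADDUCTS",
    "MassMeasurement",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_from_mz",
    "mass_error",
]

# Principal-isotope masses (Da). 12C is exactly 12 by definition; the rest
# are IUPAC/CODATA values. The supported element set is the in-silico
# formula-generation alphabet (C, H, O, N, P, S, F, Cl, Br) plus Si, which
# siloxane surfactants require.
ATOMIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "Si": 27.9769265325,
}

# Ion-mass conventions: the proton is an H atom minus an electron; chloride
# attachment adds a Cl atom plus an electron.
ELECTRON_MASS = 0.00054858
PROTON_MASS = 1.007276
CHLORIDE_MASS = 34.969402


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition as an element -> count map.

    Invariants: all elements belong to :data:`ATOMIC_MASS`, all counts are
    positive, and the map is non-empty.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("empty formula")
        for element, count in self.counts.items():
            if element not in ATOMIC_MASS:
                raise FormulaError(f"unsupported element {element!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"invalid count {count!r} for element {element!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    def hill(self) -> str:
        """Format in Hill order: C, then H, then the rest alphabetically."""
        items = dict(self.counts)
        ordered = []
        if "C" in items:
            ordered.append(("C", items.pop("C")))
            if "H" in items:
                ordered.append(("H", items.pop("H")))
        ordered.extend(sorted(items.items()))
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in ordered)

    def combine(self, other: "MolecularFormula") -> "MolecularFormula":
        """Element-wise sum of two compositions."""
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C6H4N2O5"``.

    No isotopes, charges, or parentheses; an absent multiplier means 1.
    Repeated element symbols accumulate.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed token at {text[pos:]!r} in {text!r}")
        element, digits = match.groups()
        if element not in ATOMIC_MASS:
            raise FormulaError(f"unknown element {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da (sum of principal-isotope masses)."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula.counts.items())


@dataclass(frozen=True)
class Adduct:
    """A single-charge ionization adduct: m/z = neutral mass + mass_shift."""

    name: str
    mass_shift: float
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"invalid polarity {self.polarity!r}")


# The three adducts the workflow considers: protonation, deprotonation and
# chloride attachment (the latter only seen in negative mode, e.g. for
# sulfonic acids). The registry is a plain dict and may be extended.
ADDUCTS: Dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +PROTON_MASS, "positive"),
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, "negative"),
    "[M+Cl]-": Adduct("[M+Cl]-", +CHLORIDE_MASS, "negative"),
}


def adduct_mz(neutral_mass: float, adduct: Adduct) -> float:
    """m/z of the singly-charged ion formed from a neutral molecule."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return neutral_mass + adduct.mass_shift


def neutral_from_mz(mz: float, adduct: Adduct) -> float:
    """Inverse of :func:`adduct_mz`."""
    return mz - adduct.mass_shift


@dataclass(frozen=True)
class MassMeasurement:
    """An observed/theoretical m/z pair with its signed errors."""

    observed_mz: float
    theoretical_mz: float
    error_mda: float
    error_ppm: float


def mass_error(observed: float, theoretical: float) -> MassMeasurement:
    """Signed mass error in mDa and ppm of an observed vs theoretical m/z."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    delta = observed - theoretical
    return MassMeasurement(
        observed_mz=observed,
        theoretical_mz=theoretical,
        error_mda=delta * 1e3,
        error_ppm=delta / theoretical * 1e6,
    )
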