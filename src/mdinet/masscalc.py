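"""Exact monoisotopic mass arithmetic for small-molecule annotation.

All annotation in this package is done in the currency of elemental
compositions over the alphabet C, H, N, O, P, S, Na — the elements a
positive-mode direct-infusion FT-ICR measurement of a polar metabolome can
realistically carry at z = 1.  This module provides formula parsing and
printing (Hill order), monoisotopic masses, protonated/sodiated adduct m/z
for nM multimers, ppm errors, and the construction of biochemical mass
differences (the exact mass gained by a reaction, e.g. a condensation).

Atomic masses are CODATA/IUPAC monoisotopic values (AME2020), hard-coded to
>= 9 decimal places.  Ionisation is handled with the proton mass for [M+H]+
and the sodium atomic mass minus the electron mass for [M+Na]+, so printed
calibrant values (e.g. arginine [M+H]+ = 175.11895) are reproduced from the
table alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_C12_SPACING",
    "MolecularFormula",
    "AdductSpec",
    "MassDifference",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "make_mass_difference",
    "load_mass_difference_list",
    "default_mass_differences",
]

# Monoisotopic atomic masses, Da (IUPAC/AME2020); 12C defines the scale.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
}

#: Supported element alphabet, in Hill order (C, H, then alphabetical).
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "Na", "O", "P", "S")

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990907
#: m(13C) - m(12C), the +1 isotopologue spacing in Da.
C13_C12_SPACING = 1.0033548378

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Elemental composition as non-negative counts over C/H/N/Na/O/P/S.

    Immutable and hashable; supports ``+`` and ``-`` (subtraction raising on
    negative counts) so that mass-difference formula deltas can be applied
    during network propagation.
    """

    counts: tuple[int, ...]  # aligned with ELEMENTS

    def __post_init__(self) -> None:
        if len(self.counts) != len(ELEMENTS):
            raise ValueError("counts must align with the element alphabet")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative element count in {self.counts}")

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "MolecularFormula":
        unknown = set(d) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unsupported element symbol(s): {sorted(unknown)}")
        return cls(tuple(int(d.get(e, 0)) for e in ELEMENTS))

    def __getitem__(self, element: str) -> int:
        return self.counts[ELEMENTS.index(element)]

    def to_dict(self) -> dict[str, int]:
        return {e: c for e, c in zip(ELEMENTS, self.counts) if c > 0}

    @property
    def mass(self) -> float:
        return sum(c * MONOISOTOPIC_MASS[e] for e, c in zip(ELEMENTS, self.counts))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(tuple(a + b for a, b in zip(self.counts, other.counts)))

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        # raises ValueError through __post_init__ if any count goes negative
        return MolecularFormula(tuple(a - b for a, b in zip(self.counts, other.counts)))

    def subtractable(self, other: "MolecularFormula") -> bool:
        return all(a >= b for a, b in zip(self.counts, other.counts))

    def hill(self) -> str:
        """Canonical Hill-order string; empty composition prints as ''."""
        parts = []
        for e in ELEMENTS:
            c = self[e]
            if c == 0:
                continue
            parts.append(e if c == 1 else f"{e}{c}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill() or "(empty)"


EMPTY_FORMULA = MolecularFormula((0,) * len(ELEMENTS))


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C6H14N4O2"``.

    Only the supported element alphabet is accepted; no isotope labels,
    charges or parentheses.  The empty string parses to the empty formula.
    Round-trips through :meth:`MolecularFormula.hill`.
    """
    if text is None:
        raise ValueError("formula string is None")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unsupported element symbol {sym!r} in {text!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return MolecularFormula.from_dict(counts)


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    """Neutral monoisotopic mass in Da; the empty formula has mass 0."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f.mass


@dataclass(frozen=True)
class AdductSpec:
    """Singly charged positive adduct: [nM+H]+ or [nM+Na]+.

    The study instrument runs positive ESI restricted to z = 1, so the charge
    is fixed; only the multimer count and the charge carrier vary.
    """

    n: int = 1
    carrier: str = "proton"  # "proton" | "sodium"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("multimer count must be >= 1")
        if self.carrier not in ("proton", "sodium"):
            raise ValueError(f"unsupported charge carrier {self.carrier!r}")

    @property
    def z(self) -> int:
        return 1

    @property
    def carrier_mass(self) -> float:
        if self.carrier == "proton":
            return PROTON_MASS
        return MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS


PROTONATED = AdductSpec(1, "proton")
SODIATED = AdductSpec(1, "sodium")


def adduct_mz(f: MolecularFormula | str, adduct: AdductSpec = PROTONATED) -> float:
    """m/z of [nM+H]+ or [nM+Na]+ for a neutral formula M."""
    m = monoisotopic_mass(f)
    return (adduct.n * m + adduct.carrier_mass) / adduct.z


def neutral_mass_from_mz(mz: float, adduct: AdductSpec = PROTONATED) -> float:
    """Invert :func:`adduct_mz` for monomers (n must be 1)."""
    if adduct.n != 1:
        raise ValueError("neutralisation is only defined for monomer adducts")
    return mz * adduct.z - adduct.carrier_mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class MassDifference:
    """A named biochemical transformation and its exact neutral mass delta.

    ``delta_mass = mass(formula_gained) - mass(formula_lost)`` and is positive
    by convention: mass-difference edges always point from the lower-mass to
    the higher-mass feature.  E.g. condensation of oleic acid gains C18H34O2
    and loses H2O, a delta of 264.245316 Da.
    """

    name: str
    formula_gained: MolecularFormula
    formula_lost: MolecularFormula

    @property
    def delta_mass(self) -> float:
        return self.formula_gained.mass - self.formula_lost.mass

    def net_gain(self) -> tuple[MolecularFormula, MolecularFormula]:
        """Reduced (gain, loss) pair with common atoms cancelled."""
        g, l = list(self.formula_gained.counts), list(self.formula_lost.counts)
        gain = tuple(max(a - b, 0) for a, b in zip(g, l))
        loss = tuple(max(b - a, 0) for a, b in zip(g, l))
        return MolecularFormula(gain), MolecularFormula(loss)

    def apply(self, f: MolecularFormula, forward: bool = True) -> MolecularFormula | None:
        """Apply the formula delta to ``f`` (forward = towards higher mass).

        Returns None if the subtraction would drive a count negative.
        """
        gain, loss = self.net_gain()
        add, sub = (gain, loss) if forward else (loss, gain)
        if not f.subtractable(sub):
            return None
        return f + add - sub


def make_mass_difference(
    name: str,
    gained: MolecularFormula | str,
    lost: MolecularFormula | str = EMPTY_FORMULA,
) -> MassDifference:
    """Build a :class:`MassDifference`; the delta must be strictly positive."""
    if isinstance(gained, str):
        gained = parse_formula(gained)
    if isinstance(lost, str):
        lost = parse_formula(lost)
    md = MassDifference(name, gained, lost)
    if md.delta_mass <= 0:
        raise ValueError(
            f"mass difference {name!r} has non-positive delta "
            f"({md.delta_mass:.6f} Da); list convention is low->high mass"
        )
    return md


def load_mass_difference_list(path) -> list[MassDifference]:
    """Read a TSV with columns name, formula_gained, formula_lost.

    An empty/missing formula_lost cell means a plain addition.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "formula_gained", "formula_lost"}
    if not required.issubset(df.columns):
        raise ValueError(f"mass-difference list must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            make_mass_difference(
                row.name,
                parse_formula(row.formula_gained),
                parse_formula(row.formula_lost) if row.formula_lost else EMPTY_FORMULA,
            )
        )
    return out


def default_mass_differences() -> list[MassDifference]:
    """The packaged default list of ~50 common biochemical transformations.

    Covers condensations/additions of water, CO2, ammonia, methylene, ketene,
    oxygen, fatty-acyl chains C12-C24 (0-6 double bonds), hexose, phosphate,
    sulfate, glycine, taurine, glucuronate and steroid-backbone conjugations.
    A curated functional stand-in for larger proprietary reaction lists; users
    can supply their own TSV via :func:`load_mass_difference_list`.
    """
    with resources.files("mdinet.data").joinpath("mass_differences.tsv").open() as fh:
        return load_mass_difference_list(fh)
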