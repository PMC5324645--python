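"""Exact-mass chemistry for small-molecule formula assignment.

Monoisotopic masses, ion/neutral conversion for protonated/deprotonated
species, double bond equivalents, the modified aromaticity index, elemental
ratios, and Kendrick (CH2-based) mass coordinates with the z* series index.

All masses are in Da (Th for m/z at |z| = 1).  The isotope-mass table is
pinned inside the package so results are bit-stable across environments.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "CH2_MASS",
    "C13_C12_DELTA",
    "MolecularFormula",
    "Peak",
    "KendrickCoords",
    "Polarity",
    "IonMode",
    "NEGATIVE_H",
    "POSITIVE_H",
    "InvalidIonError",
    "exact_mass",
    "ion_mz",
    "neutral_mass",
    "dbe",
    "ai_mod",
    "elemental_ratios",
    "kendrick",
    "ppm_error",
]

#: Most-abundant-isotope masses, Da (pinned; CODATA/AME-derived values).
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

ELECTRON_MASS = 0.0005486
#: Mass of H+ (1H minus one electron), Da.
PROTON_MASS = 1.0072765
#: Mass of one CH2 repeat unit, Da (the Kendrick base).
CH2_MASS = ELEMENT_MASSES["C"] + 2.0 * ELEMENT_MASSES["H"]
#: 13C - 12C mass difference, Da (pinned).
C13_C12_DELTA = 1.0033548

_HILL_ORDER = ("C", "H", "N", "O", "P", "S")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidIonError(ValueError):
    """Requested ion cannot be formed from the neutral formula."""


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Element counts of a neutral molecule (C, H, N, O, S, P only)."""

    c: int
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"element count {name}={v!r} must be a non-negative int")
        if self.c < 1:
            raise ValueError("formula must contain at least one carbon")

    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s, "P": self.p}

    def hill(self) -> str:
        """Hill-notation string: C, H, then remaining elements alphabetically.

        Count 1 is rendered without a digit ("CH4O", not "C1H4O1").
        """
        parts = []
        for el in _HILL_ORDER:
            cnt = self.counts()[el]
            if cnt == 0:
                continue
            parts.append(el if cnt == 1 else f"{el}{cnt}")
        return "".join(parts)

    def __str__(self) -> str:  # round-trips through parse()
        return self.hill()

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style formula string ("C9H10O5") back to counts."""
        text = text.strip()
        if not text:
            raise ValueError("empty formula string")
        counts: dict[str, int] = {el: 0 for el in _HILL_ORDER}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            el, digits = m.group(1), m.group(2)
            if el not in counts:
                raise ValueError(f"unsupported element {el!r} in {text!r}")
            counts[el] += int(digits) if digits else 1
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"],
                   o=counts["O"], s=counts["S"], p=counts["P"])

    def shift_ch2(self, k: int) -> "MolecularFormula":
        """Return this formula plus k CH2 units (k may be negative).

        Raises ValueError if the result would have c < 1 or h < 0.
        """
        return MolecularFormula(c=self.c + k, h=self.h + 2 * k,
                                n=self.n, o=self.o, s=self.s, p=self.p)

    @property
    def heteroatoms(self) -> int:
        return self.n + self.s + self.p


@dataclass(frozen=True)
class Peak:
    """One centroid: m/z in Th and an arbitrary-unit intensity."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


class Polarity(enum.Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"


@dataclass(frozen=True)
class IonMode:
    """Ionisation mode: deprotonation [M-H]- or protonation [M+H]+."""

    polarity: Polarity

    @property
    def mass_shift(self) -> float:
        """Neutral mass + shift = ion m/z."""
        return -PROTON_MASS if self.polarity is Polarity.NEGATIVE else PROTON_MASS


NEGATIVE_H = IonMode(Polarity.NEGATIVE)
POSITIVE_H = IonMode(Polarity.POSITIVE)


def exact_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da."""
    return (f.c * ELEMENT_MASSES["C"] + f.h * ELEMENT_MASSES["H"]
            + f.n * ELEMENT_MASSES["N"] + f.o * ELEMENT_MASSES["O"]
            + f.s * ELEMENT_MASSES["S"] + f.p * ELEMENT_MASSES["P"])


def ion_mz(f: MolecularFormula, mode: IonMode) -> float:
    """m/z of [M-H]- or [M+H]+ in Th, electron mass included via PROTON_MASS."""
    if mode.polarity is Polarity.NEGATIVE and f.h < 1:
        raise InvalidIonError(f"cannot deprotonate {f}: no hydrogen")
    return exact_mass(f) + mode.mass_shift


def neutral_mass(mz: float, mode: IonMode) -> float:
    """Exact inverse of ion_mz at the mass level."""
    return mz - mode.mass_shift


def dbe(f: MolecularFormula) -> float:
    """Double bond equivalents: 1 + C - H/2 + N/2 + P/2 (O, S neutral).

    May be half-integer for radical/impossible formulae; callers filter.
    """
    return 1.0 + f.c - f.h / 2.0 + f.n / 2.0 + f.p / 2.0


def ai_mod(f: MolecularFormula) -> float:
    """Modified aromaticity index.

    AI_mod = (1 + C - O/2 - S - H/2) / (C - O/2 - S - N - P), treating half
    the oxygen as carbonyl-like.  Degenerate cases (non-positive denominator
    or negative numerator) clamp to 0 so plots stay total functions.
    """
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * f.h
    den = f.c - 0.5 * f.o - f.s - f.n - f.p
    if den <= 0 or num < 0:
        return 0.0
    return num / den


def elemental_ratios(f: MolecularFormula) -> tuple[float, float, float]:
    """(H/C, O/C, N/C) ratios."""
    return (f.h / f.c, f.o / f.c, f.n / f.c)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class KendrickCoords:
    """CH2-normalised Kendrick coordinates of one m/z value.

    kmd = nominal_kendrick_mass - kendrick_mass (positive for typical CHO
    ions, the dominant petroleomics sign convention); z* = (nominal IUPAC
    mass mod 14) - 14.  Members of one CH2 homologous series share both.
    """

    kendrick_mass: float
    nominal_kendrick_mass: int
    kmd: float
    z_star: int


def kendrick(mz: float) -> KendrickCoords:
    """Kendrick coordinates for an observed m/z (CH2 base)."""
    if not mz > 0:
        raise ValueError(f"mz must be positive, got {mz}")
    km = mz * 14.0 / CH2_MASS
    nominal = _round_half_up(km)
    z_star = _round_half_up(mz) % 14 - 14
    return KendrickCoords(kendrick_mass=km, nominal_kendrick_mass=nominal,
                          kmd=nominal - km, z_star=z_star)


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative mass error in parts per million."""
    if not calculated > 0:
        raise ValueError("calculated mass must be positive")
    return (observed - calculated) / calculated * 1e6
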