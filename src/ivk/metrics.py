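"""Heteroatom class labels, van Krevelen compound-class regions, glyph sizing.

The heteroatom class of a formula is the canonical text of its non-CH
element counts ("O7", "N1O5", "CH" for pure hydrocarbons); the class
distribution of an assignment list is the per-class count and summed
relative intensity, the standard petroleomics summary plot.

Van Krevelen regions are configurable half-open rectangles in
(O/C, H/C) space; the defaults cover the three classic anchors — lipid-like
(low O/C, H/C near 2), carbohydrate-like (O/C near 1, H/C near 2) and
condensed-aromatic-like (low O/C, H/C below 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .chem import MolecularFormula

__all__ = [
    "HeteroatomClass",
    "VKRegion",
    "DEFAULT_VK_REGIONS",
    "class_of",
    "class_distribution",
    "vk_region",
    "glyph_size",
]

_CLASS_ORDER = ("N", "O", "S", "P")


def class_of(f: MolecularFormula) -> str:
    """Canonical heteroatom-class label, e.g. "O5", "N1O3"; "CH" if none.

    Elements appear in fixed N, O, S, P order, each with its explicit count.
    """
    counts = {"N": f.n, "O": f.o, "S": f.s, "P": f.p}
    label = "".join(f"{el}{counts[el]}" for el in _CLASS_ORDER if counts[el] > 0)
    return label or "CH"


# kept as an alias for the domain-type name
HeteroatomClass = str


def class_distribution(assignments) -> pd.DataFrame:
    """Per-class counts and intensity shares, sorted by count descending.

    ``assignments`` is an iterable of objects with ``formula`` and a
    ``peak.intensity`` (the assigner's AssignedPeak).  Returns columns
    [class, count, rel_intensity] where rel_intensity is each class's share
    of the total assigned intensity (all zero when intensity sums to 0).
    """
    rows = [(class_of(a.formula), a.peak.intensity) for a in assignments]
    if not rows:
        return pd.DataFrame(columns=["class", "count", "rel_intensity"])
    df = pd.DataFrame(rows, columns=["class", "intensity"])
    total = df["intensity"].sum()
    g = df.groupby("class", sort=False).agg(count=("class", "size"),
                                            intensity=("intensity", "sum"))
    g["rel_intensity"] = g["intensity"] / total if total > 0 else 0.0
    g = g.drop(columns="intensity").reset_index()
    return g.sort_values(["count", "class"], ascending=[False, True],
                         ignore_index=True)


@dataclass(frozen=True)
class VKRegion:
    """One half-open rectangle [min, max) in (O/C, H/C) space."""

    label: str
    oc_min: float
    oc_max: float
    hc_min: float
    hc_max: float

    def contains(self, oc: float, hc: float) -> bool:
        return (self.oc_min <= oc < self.oc_max) and (self.hc_min <= hc < self.hc_max)


#: Default compound-class boxes, tested in order; first hit wins.
DEFAULT_VK_REGIONS: tuple[VKRegion, ...] = (
    VKRegion("lipid-like", 0.0, 0.2, 1.7, 2.3),
    VKRegion("carbohydrate-like", 0.7, 1.3, 1.7, 2.3),
    VKRegion("condensed-aromatic-like", 0.0, 0.2, 0.2, 1.0),
)

UNCLASSIFIED = "unclassified"


def vk_region(f: MolecularFormula,
              regions: tuple[VKRegion, ...] = DEFAULT_VK_REGIONS) -> str:
    """Compound-class region label for a formula's (O/C, H/C) point."""
    oc = f.o / f.c
    hc = f.h / f.c
    for region in regions:
        if region.contains(oc, hc):
            return region.label
    return UNCLASSIFIED


def glyph_size(intensity: float, max_intensity: float,
               s_min: float = 3.0, s_max: float = 18.0,
               *, scaling: str = "sqrt") -> float:
    """Display size for a glyph encoding relative abundance.

    sqrt scaling (default) makes glyph *area* linear in abundance; "linear"
    maps intensity directly.  The base peak maps to s_max, zero to s_min.
    """
    if not max_intensity > 0:
        raise ValueError("max_intensity must be positive")
    if not 0 <= intensity <= max_intensity:
        raise ValueError("need 0 <= intensity <= max_intensity")
    frac = intensity / max_intensity
    if scaling == "sqrt":
        frac = math.sqrt(frac)
    elif scaling != "linear":
        raise ValueError(f"unknown scaling {scaling!r}")
    return s_min + (s_max - s_min) * frac
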