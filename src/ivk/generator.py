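"""Exhaustive candidate-formula generation with heuristic plausibility rules.

Given a target neutral mass and a ppm tolerance, enumerate every CHNOSP
formula inside the configured element ranges whose monoisotopic mass falls
in the window and which passes the enabled chemical-plausibility rules
(valence cap, elemental-ratio bounds, integer non-negative DBE,
even-electron parity).  Also provides the minimum-candidate-spacing
utility used to choose assignment error thresholds: the smallest mass gap
between any two surviving candidates near a given m/z.

The search iterates heteroatom counts in the outer loops and solves the
feasible hydrogen range analytically from the mass window, but is
output-equivalent (membership and order) to a naive nested-loop scan.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .chem import (
    ELEMENT_MASSES,
    IonMode,
    MolecularFormula,
    dbe,
    neutral_mass,
    ppm_error,
)

__all__ = [
    "ElementRanges",
    "HeuristicRules",
    "Candidate",
    "SpacingResult",
    "CandidateCapExceeded",
    "generate_candidates",
    "min_candidate_spacing",
    "passes_rules",
]

_M_H = ELEMENT_MASSES["H"]


class CandidateCapExceeded(RuntimeError):
    """The mass window admits more candidates than the configured cap."""


@dataclass(frozen=True)
class ElementRanges:
    """Inclusive [min, max] count ranges per element.

    Defaults target negative-mode natural-organic-matter work: C 1-100,
    H 0-200, N 0-5, O 0-30, S 0-2, P 0-0.
    """

    c: tuple[int, int] = (1, 100)
    h: tuple[int, int] = (0, 200)
    n: tuple[int, int] = (0, 5)
    o: tuple[int, int] = (0, 30)
    s: tuple[int, int] = (0, 2)
    p: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValueError(f"bad range for {name}: ({lo}, {hi})")

    @classmethod
    def parse(cls, text: str) -> "ElementRanges":
        """Parse a compact range string like "C1-20H0-40O0-10".

        Elements not mentioned get the empty range (0, 0) — except C, whose
        absence means the default (1, 100) is kept only if no element at all
        is given.  Single counts ("N2") mean a fixed count.
        """
        tokens = re.findall(r"([A-Z][a-z]?)(\d+)(?:-(\d+))?", text)
        if not tokens or "".join(t[0] + t[1] + ("-" + t[2] if t[2] else "")
                                 for t in tokens) != text.replace(" ", ""):
            raise ValueError(f"cannot parse element ranges {text!r}")
        ranges: dict[str, tuple[int, int]] = {k: (0, 0) for k in "CHNOSP"}
        for el, lo, hi in tokens:
            if el not in ranges:
                raise ValueError(f"unsupported element {el!r}")
            ranges[el] = (int(lo), int(hi) if hi else int(lo))
        return cls(c=ranges["C"], h=ranges["H"], n=ranges["N"],
                   o=ranges["O"], s=ranges["S"], p=ranges["P"])


@dataclass(frozen=True)
class HeuristicRules:
    """Chemical-plausibility filters applied to every candidate.

    Defaults follow heuristic-filtering practice for natural organic
    matter: H/C in [0.3, 3.0], O/C <= 1.2, N/C <= 0.5, S/C <= 0.2, a
    senior-type valence cap H <= 2C + 2 + N + P, and an integer,
    non-negative DBE (the even-electron parity condition for neutral
    molecules).  Every rule is individually toggleable.
    """

    hc_min: float = 0.3
    hc_max: float = 3.0
    oc_max: float = 1.2
    nc_max: float = 0.5
    sc_max: float = 0.2
    require_integer_dbe: bool = True
    dbe_min: float = 0.0
    parity_rule: bool = True
    valence_cap: bool = True

    def __post_init__(self) -> None:
        if self.hc_min < 0 or self.hc_min >= self.hc_max:
            raise ValueError("need 0 <= hc_min < hc_max")
        for name in ("oc_max", "nc_max", "sc_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def passes_rules(f: MolecularFormula, rules: HeuristicRules) -> bool:
    """True iff the formula passes every enabled heuristic rule."""
    c = f.c
    if rules.valence_cap and f.h > 2 * c + 2 + f.n + f.p:
        return False
    hc = f.h / c
    if hc < rules.hc_min or hc > rules.hc_max:
        return False
    if f.o / c > rules.oc_max or f.n / c > rules.nc_max or f.s / c > rules.sc_max:
        return False
    d = dbe(f)
    if rules.require_integer_dbe and (f.h + f.n + f.p) % 2 != 0:
        return False
    if d < rules.dbe_min:
        return False
    if rules.parity_rule and ((f.h + f.n + f.p) % 2 != 0 or d < 0):
        return False
    return True


@dataclass(frozen=True)
class Candidate:
    """A candidate formula for a target neutral mass."""

    formula: MolecularFormula
    calc_mass: float
    error_ppm: float


def _sort_key(cand: Candidate):
    # |ppm| asc, then fewer heteroatoms, fewer O, lexicographic Hill string
    return (abs(cand.error_ppm), cand.formula.heteroatoms, cand.formula.o,
            cand.formula.hill())


def generate_candidates(
    target_neutral_mass: float,
    tol_ppm: float,
    ranges: ElementRanges | None = None,
    rules: HeuristicRules | None = None,
    *,
    cap: int = 10_000,
) -> list[Candidate]:
    """All rule-passing formulae with |mass error| <= tol_ppm of the target.

    Returns candidates sorted by |error_ppm| ascending (ties: fewer
    heteroatoms, then fewer oxygens, then Hill string).  Raises
    CandidateCapExceeded if more than ``cap`` candidates survive.
    """
    if not target_neutral_mass > 0:
        raise ValueError("target_neutral_mass must be positive")
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be positive")
    ranges = ranges or ElementRanges()
    rules = rules or HeuristicRules()

    m_lo = target_neutral_mass * (1.0 - tol_ppm * 1e-6)
    m_hi = target_neutral_mass * (1.0 + tol_ppm * 1e-6)
    out: list[Candidate] = []

    m_c, m_n, m_o, m_s, m_p = (ELEMENT_MASSES[e] for e in "CNOSP")
    for n in range(ranges.n[0], ranges.n[1] + 1):
        mass_n = n * m_n
        if mass_n > m_hi:
            break
        for s in range(ranges.s[0], ranges.s[1] + 1):
            mass_ns = mass_n + s * m_s
            if mass_ns > m_hi:
                break
            for p in range(ranges.p[0], ranges.p[1] + 1):
                mass_nsp = mass_ns + p * m_p
                if mass_nsp > m_hi:
                    break
                for o in range(ranges.o[0], ranges.o[1] + 1):
                    mass_nspo = mass_nsp + o * m_o
                    if mass_nspo > m_hi:
                        break
                    for c in range(ranges.c[0], ranges.c[1] + 1):
                        heavy = mass_nspo + c * m_c
                        if heavy > m_hi:
                            break
                        # analytic hydrogen window for this heavy-atom core
                        h_lo = max(ranges.h[0], math.ceil((m_lo - heavy) / _M_H - 1e-9))
                        h_hi = min(ranges.h[1], math.floor((m_hi - heavy) / _M_H + 1e-9))
                        for h in range(h_lo, h_hi + 1):
                            mass = heavy + h * _M_H
                            if mass < m_lo or mass > m_hi:
                                continue
                            f = MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p)
                            if not passes_rules(f, rules):
                                continue
                            out.append(Candidate(
                                formula=f, calc_mass=mass,
                                error_ppm=ppm_error(target_neutral_mass, mass)))
                            if len(out) > cap:
                                raise CandidateCapExceeded(
                                    f"> {cap} candidates at {target_neutral_mass} Da "
                                    f"± {tol_ppm} ppm")
    out.sort(key=_sort_key)
    return out


@dataclass(frozen=True)
class SpacingResult:
    """Minimum mass gap between two candidates in a window around an m/z.

    gap_da / gap_ppm are +inf when fewer than two candidates survive.
    """

    gap_da: float
    gap_ppm: float
    pair: tuple[Candidate, Candidate] | None
    candidates: list[Candidate] = field(repr=False, default_factory=list)


def min_candidate_spacing(
    target_mz: float,
    mode: IonMode | None,
    window_ppm: float,
    ranges: ElementRanges | None = None,
    rules: HeuristicRules | None = None,
    *,
    cap: int = 10_000,
) -> SpacingResult:
    """Smallest |mass difference| between distinct candidates near an m/z.

    ``mode`` of None treats target_mz as a neutral mass.  The gap quantifies
    how far apart plausible formulae sit at this m/z — i.e. how tight an
    assignment tolerance must be to be unambiguous.
    """
    if not window_ppm > 0:
        raise ValueError("window_ppm must be positive")
    target = neutral_mass(target_mz, mode) if mode is not None else target_mz
    cands = generate_candidates(target, window_ppm, ranges, rules, cap=cap)
    if len(cands) < 2:
        return SpacingResult(math.inf, math.inf, None, cands)
    by_mass = sorted(cands, key=lambda cand: cand.calc_mass)
    best = None
    for a, b in zip(by_mass, by_mass[1:]):
        gap = b.calc_mass - a.calc_mass
        if best is None or gap < best[0]:
            best = (gap, (a, b))
    gap_da, pair = best
    return SpacingResult(gap_da, gap_da / target * 1e6, pair, cands)
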