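"""Batch molecular-formula assignment via Kendrick homologous series.

The workflow mirrors standard petroleomics practice:

1. Every peak gets Kendrick coordinates; peaks sharing z* and (within a
   tolerance) the Kendrick mass defect form CH2 homologous series
   (single-linkage clustering on KMD within each z* stratum).
2. Each series is seeded from its least ambiguous member — the one with the
   fewest candidate formulae from the exhaustive generator at the tight
   "seed" tolerance (ties broken by intensity).  The best candidate becomes
   the seed formula.
3. The seed formula propagates out along the series in +-CH2 steps; a member
   is accepted only if the propagated formula reproduces its m/z within the
   looser "member" tolerance and passes every heuristic rule.
4. The procedure repeats on the still-unassigned remainder until a fixpoint:
   this rescues genuine series that the first-pass clustering merged with a
   neighbour of nearly identical KMD.
5. Remaining peaks are searched for 13C1 isotopologue satellites of the
   assigned monoisotopic peaks (mass offset +1.0033548 Da, intensity
   consistent with ~1.07% per carbon).

The result is the three-part partition used throughout the package:
monoisotopic assignments, isotopologue annotations, unassigned peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import metrics
from .chem import (
    C13_C12_DELTA,
    CH2_MASS,
    InvalidIonError,
    IonMode,
    KendrickCoords,
    MolecularFormula,
    NEGATIVE_H,
    Peak,
    dbe,
    ai_mod,
    ion_mz,
    kendrick,
    neutral_mass,
    ppm_error,
)
from .generator import (
    Candidate,
    CandidateCapExceeded,
    ElementRanges,
    HeuristicRules,
    generate_candidates,
    passes_rules,
)

__all__ = [
    "AssignmentConfig",
    "HomologousSeries",
    "AssignedPeak",
    "IsotopologueAnnotation",
    "AssignmentSet",
    "group_series",
    "assign",
    "annotate_isotopologues",
]

logger = logging.getLogger(__name__)

#: Natural 13C abundance ratio per carbon atom (13C/12C ~ 1.07%).
C13_ABUNDANCE_RATIO = 0.0107
#: Accepted observed/expected isotopologue intensity band (deliberately
#: loose: centroid intensities of weak satellites are noisy).
ISO_RATIO_BAND = (0.2, 3.0)


@dataclass(frozen=True)
class AssignmentConfig:
    """Tolerances, ion mode, element ranges and rules for one assignment run.

    tol_ppm_seed gates the exhaustive-generator search that seeds each
    series; tol_ppm_member gates acceptance of CH2-propagated members (and
    isotopologue mass matching).  kmd_tol is the single-linkage threshold
    for series clustering.  min_rel_intensity (fraction of the base peak)
    defaults to 0 so the low-abundance "grass" is kept.
    """

    tol_ppm_seed: float = 0.5
    tol_ppm_member: float = 1.0
    kmd_tol: float = 0.0005
    mode: IonMode = NEGATIVE_H
    ranges: ElementRanges = field(default_factory=ElementRanges)
    rules: HeuristicRules = field(default_factory=HeuristicRules)
    min_rel_intensity: float = 0.0
    iso_ratio_band: tuple[float, float] = ISO_RATIO_BAND
    candidate_cap: int = 10_000
    max_passes: int = 10

    def __post_init__(self) -> None:
        if self.tol_ppm_seed > self.tol_ppm_member:
            raise ValueError("tol_ppm_seed must be <= tol_ppm_member")
        if not self.kmd_tol > 0:
            raise ValueError("kmd_tol must be positive")


@dataclass(frozen=True)
class HomologousSeries:
    """Peaks sharing z* and KMD, ordered by m/z; indices into the input list."""

    z_star: int
    kmd_centroid: float
    member_peak_indices: tuple[int, ...]


@dataclass(frozen=True)
class AssignedPeak:
    """A peak bound to a neutral formula, with all plot-ready derived values."""

    peak: Peak
    formula: MolecularFormula
    calc_mz: float
    error_ppm: float
    provenance: str  # "seed" | "propagated"
    dbe: float
    ai_mod: float
    hc: float
    oc: float
    class_label: str
    kendrick: KendrickCoords


@dataclass(frozen=True)
class IsotopologueAnnotation:
    """A satellite peak attributed to a 13C1 isotopologue of an assigned peak."""

    peak: Peak
    parent_mz: float
    parent_formula: MolecularFormula
    label: str  # e.g. "13C1"
    observed_ratio: float  # satellite / parent intensity
    expected_ratio: float  # c * 0.0107


@dataclass
class AssignmentSet:
    """The three-file partition of an input peak list."""

    monoisotopic: list[AssignedPeak]
    isotopologues: list[IsotopologueAnnotation]
    unassigned: list[Peak]

    def __len__(self) -> int:
        return len(self.monoisotopic) + len(self.isotopologues) + len(self.unassigned)


def _make_assigned(peak: Peak, formula: MolecularFormula, calc_mz: float,
                   err: float, provenance: str) -> AssignedPeak:
    hc, oc, _ = (formula.h / formula.c, formula.o / formula.c, 0)
    return AssignedPeak(
        peak=peak, formula=formula, calc_mz=calc_mz, error_ppm=err,
        provenance=provenance, dbe=dbe(formula), ai_mod=ai_mod(formula),
        hc=hc, oc=oc, class_label=metrics.class_of(formula),
        kendrick=kendrick(peak.mz))


def group_series(peaks: list[Peak], cfg: AssignmentConfig) -> list[HomologousSeries]:
    """Cluster peaks into CH2 homologous series by shared z* and KMD.

    Within each z* stratum, single-linkage clustering on KMD with link
    threshold cfg.kmd_tol (exact in 1D: sort by KMD and split at gaps
    larger than the threshold).  Singleton series are allowed.  Indices in
    the result refer to positions in the input list.
    """
    coords = [kendrick(p.mz) for p in peaks]
    strata: dict[int, list[int]] = {}
    for i, k in enumerate(coords):
        strata.setdefault(k.z_star, []).append(i)

    out: list[HomologousSeries] = []
    for z in sorted(strata):
        idx = sorted(strata[z], key=lambda i: (coords[i].kmd, peaks[i].mz))
        cluster: list[int] = [idx[0]]
        for i in idx[1:]:
            if coords[i].kmd - coords[cluster[-1]].kmd <= cfg.kmd_tol:
                cluster.append(i)
            else:
                out.append(_finish_series(z, cluster, coords, peaks))
                cluster = [i]
        out.append(_finish_series(z, cluster, coords, peaks))
    return out


def _finish_series(z: int, cluster: list[int], coords, peaks) -> HomologousSeries:
    members = tuple(sorted(cluster, key=lambda i: peaks[i].mz))
    centroid = sum(coords[i].kmd for i in cluster) / len(cluster)
    return HomologousSeries(z_star=z, kmd_centroid=centroid,
                            member_peak_indices=members)


def _assign_series_pass(
    peaks: list[Peak], indices: list[int], cfg: AssignmentConfig
) -> dict[int, AssignedPeak]:
    """One seed-and-propagate pass over the peaks at the given indices.

    Returns a mapping from peak index to its accepted assignment.  Conflicts
    (a peak reachable from two series) resolve by smallest |error_ppm|, then
    fewer heteroatoms, then Hill-string order.
    """
    sub = [peaks[i] for i in indices]
    series_list = group_series(sub, cfg)
    winners: dict[int, AssignedPeak] = {}

    for series in sorted(series_list, key=lambda s: (s.z_star, s.kmd_centroid)):
        members = [sub[j] for j in series.member_peak_indices]
        cands: list[list[Candidate]] = []
        capped = False
        for pk in members:
            try:
                cands.append(generate_candidates(
                    neutral_mass(pk.mz, cfg.mode), cfg.tol_ppm_seed,
                    cfg.ranges, cfg.rules, cap=cfg.candidate_cap))
            except CandidateCapExceeded:
                logger.warning("candidate cap exceeded at m/z %.5f; "
                               "series left unassigned", pk.mz)
                capped = True
                break
        if capped:
            continue
        seedable = [j for j, cl in enumerate(cands) if cl]
        if not seedable:
            continue
        # least ambiguous member first; ties -> most intense
        seed_j = min(seedable, key=lambda j: (len(cands[j]), -members[j].intensity))
        seed_peak = members[seed_j]
        seed_formula = cands[seed_j][0].formula

        for j, pk in enumerate(members):
            k = round((pk.mz - seed_peak.mz) / CH2_MASS)
            try:
                f = seed_formula.shift_ch2(k)
                calc = ion_mz(f, cfg.mode)
            except (ValueError, InvalidIonError):
                continue
            err = ppm_error(pk.mz, calc)
            if abs(err) > cfg.tol_ppm_member or not passes_rules(f, cfg.rules):
                continue
            ap = _make_assigned(pk, f, calc, err,
                                "seed" if j == seed_j else "propagated")
            gi = indices[series.member_peak_indices[j]]
            prev = winners.get(gi)
            if prev is None or _conflict_key(ap) < _conflict_key(prev):
                winners[gi] = ap
    return winners


def _conflict_key(ap: AssignedPeak):
    return (abs(ap.error_ppm), ap.formula.heteroatoms, ap.formula.hill())


def assign(peaks: list[Peak], cfg: AssignmentConfig | None = None) -> AssignmentSet:
    """Assign formulae to a whole centroid peak list.

    Deterministic given inputs and config.  The returned AssignmentSet's
    three parts partition the input list (disjoint and exhaustive).
    """
    cfg = cfg or AssignmentConfig()
    if not peaks:
        return AssignmentSet([], [], [])
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].mz, -peaks[i].intensity))
    peaks = [peaks[i] for i in order]

    base = max(p.intensity for p in peaks)
    threshold = cfg.min_rel_intensity * base
    eligible = [i for i, p in enumerate(peaks) if p.intensity >= threshold]

    assigned: dict[int, AssignedPeak] = {}
    remaining = eligible
    for _ in range(cfg.max_passes):
        new = _assign_series_pass(peaks, remaining, cfg)
        if not new:
            break
        assigned.update(new)
        remaining = [i for i in remaining if i not in assigned]
        if not remaining:
            break

    mono = [assigned[i] for i in sorted(assigned)]
    leftovers = [peaks[i] for i in range(len(peaks)) if i not in assigned]
    isos, unassigned = annotate_isotopologues(mono, leftovers, cfg)
    return AssignmentSet(monoisotopic=mono, isotopologues=isos,
                         unassigned=unassigned)


def annotate_isotopologues(
    assigned: list[AssignedPeak], leftovers: list[Peak],
    cfg: AssignmentConfig | None = None,
) -> tuple[list[IsotopologueAnnotation], list[Peak]]:
    """Attribute leftover peaks to 13C1 satellites of assigned peaks.

    A leftover matches a parent when it sits at parent m/z + 1.0033548
    within tol_ppm_member AND its intensity lies inside
    iso_ratio_band x (c * 0.0107 * parent intensity).  Each leftover joins
    at most one parent — the closest in ppm among those it matches.
    """
    cfg = cfg or AssignmentConfig()
    lo_band, hi_band = cfg.iso_ratio_band
    annotations: list[IsotopologueAnnotation] = []
    remaining: list[Peak] = []
    for pk in leftovers:
        best: tuple[float, AssignedPeak] | None = None
        for parent in assigned:
            expected_mz = parent.peak.mz + C13_C12_DELTA
            err = abs(ppm_error(pk.mz, expected_mz))
            if err > cfg.tol_ppm_member:
                continue
            if parent.peak.intensity <= 0:
                continue
            expected = parent.formula.c * C13_ABUNDANCE_RATIO * parent.peak.intensity
            if not (lo_band * expected <= pk.intensity <= hi_band * expected):
                continue
            if best is None or err < best[0]:
                best = (err, parent)
        if best is None:
            remaining.append(pk)
        else:
            parent = best[1]
            expected_ratio = parent.formula.c * C13_ABUNDANCE_RATIO
            annotations.append(IsotopologueAnnotation(
                peak=pk, parent_mz=parent.peak.mz,
                parent_formula=parent.formula, label="13C1",
                observed_ratio=pk.intensity / parent.peak.intensity,
                expected_ratio=expected_ratio))
    return annotations, remaining
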