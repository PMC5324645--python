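"""Deterministic synthetic SRFA-like spectra with known ground truth.

Emulates a negative-mode electrospray FTICR spectrum of a fulvic-acid-type
complex mixture: many CH2-homologous CHO/CHNO/CHOS series between m/z 200
and 700, log-normally distributed intensities (a few dominant peaks over
dense low-abundance "grass"), ppm-scale Gaussian mass error, 13C1
isotopologue satellites at ~1.07% intensity per carbon, and unassignable
noise peaks kept well clear of every plausible formula mass.

The generator enforces two separations that make the ground truth
unambiguous: all exact (pre-perturbation) peak positions differ by at
least ``min_sep_ppm``, and series in the same z* stratum differ in
Kendrick mass defect by at least three clustering tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import (
    C13_C12_DELTA,
    IonMode,
    MolecularFormula,
    NEGATIVE_H,
    Peak,
    ion_mz,
    kendrick,
    neutral_mass,
)
from .generator import ElementRanges, HeuristicRules, generate_candidates, passes_rules

__all__ = ["MixtureSpec", "GroundTruthRecord", "GroundTruth", "InfeasibleSpec",
           "make_mixture"]


class InfeasibleSpec(ValueError):
    """The requested mixture cannot be realised in the given m/z window."""


@dataclass(frozen=True)
class MixtureSpec:
    """Study conditions for one synthetic mixture.

    Defaults emulate a typical SRFA negative-ion spectrum: 50 series of
    5-12 members across m/z 200-700, 0.2 ppm mass error, satellites on,
    100 noise peaks.
    """

    n_series: int = 50
    series_len: tuple[int, int] = (5, 12)
    class_weights: tuple[tuple[str, float], ...] = (
        ("CHO", 0.6), ("CHNO", 0.25), ("CHOS", 0.15))
    mz_range: tuple[float, float] = (200.0, 700.0)
    sigma_ppm: float = 0.2
    isotopologues: bool = True
    iso_intensity_cv: float = 0.05
    n_noise_peaks: int = 100
    intensity_median: float = 1e6
    intensity_sigma: float = 1.2
    noise_intensity_factor: float = 0.05
    mode: IonMode = NEGATIVE_H
    seed: int = 0
    min_sep_ppm: float = 2.5
    kmd_sep: float = 0.0015  # 3x the default clustering tolerance
    #: ranges used for the noise-rejection candidate check (kept wide so
    #: noise is unassignable under any plausible assignment configuration)
    noise_check_ranges: ElementRanges = field(default_factory=ElementRanges)
    noise_reject_ppm: float = 2.0


@dataclass(frozen=True)
class GroundTruthRecord:
    """Truth for one emitted peak."""

    kind: str  # "parent" | "isotopologue" | "noise"
    formula: MolecularFormula | None  # parent formula (also for satellites)
    parent_index: int | None  # peak index of the monoisotopic parent
    exact_mz: float  # pre-perturbation position


@dataclass
class GroundTruth:
    """Per-peak truth records, index-aligned with the emitted peak list."""

    records: list[GroundTruthRecord]

    def __len__(self) -> int:
        return len(self.records)


_CLASS_N_S = {"CHO": ((0, 0), (0, 0)), "CHNO": ((1, 2), (0, 0)),
              "CHOS": ((0, 0), (1, 1))}


def _draw_series(rng: np.random.Generator, spec: MixtureSpec,
                 rules: HeuristicRules) -> list[MolecularFormula] | None:
    """Draw one CH2-homologous series of rule-passing formulae, or None."""
    labels = [w[0] for w in spec.class_weights]
    probs = np.array([w[1] for w in spec.class_weights], dtype=float)
    cls = labels[rng.choice(len(labels), p=probs / probs.sum())]
    (n_lo, n_hi), (s_lo, s_hi) = _CLASS_N_S[cls]
    n = int(rng.integers(n_lo, n_hi + 1))
    s = int(rng.integers(s_lo, s_hi + 1))
    o = int(rng.integers(3, 15))
    dbe_val = int(rng.integers(2, 13))
    length = int(rng.integers(spec.series_len[0], spec.series_len[1] + 1))

    # h = 2 + 2c + n - 2*DBE keeps DBE fixed along the CH2 ladder
    def formula_at(c: int) -> MolecularFormula | None:
        h = 2 + 2 * c + n - 2 * dbe_val
        if h < 1:
            return None
        f = MolecularFormula(c=c, h=h, n=n, o=o, s=s)
        return f if passes_rules(f, rules) else None

    lo_mz, hi_mz = spec.mz_range

    def defect_ok(mz: float) -> bool:
        # keep ladders clear of the half-integer mass-defect wrap so the
        # nominal mass (and hence z*) increments by exactly 14 per CH2;
        # also keeps satellites (+1.0034) inside the same band and leaves
        # the 0.55-0.95 defect band free for unassignable noise
        frac = mz - math.floor(mz)
        return 0.02 <= frac <= 0.48

    feasible = [c for c in range(4, 60)
                if (f := formula_at(c)) is not None
                and lo_mz <= ion_mz(f, spec.mode) <= hi_mz
                and defect_ok(ion_mz(f, spec.mode))]
    if len(feasible) < spec.series_len[0]:
        return None
    # pick a contiguous run of carbons of the requested length
    runs = [c0 for c0 in feasible
            if all(c0 + k in feasible for k in range(length))]
    if not runs:
        return None
    c_start = int(runs[rng.integers(len(runs))])
    return [formula_at(c_start + k) for k in range(length)]


def make_mixture(spec: MixtureSpec) -> tuple[list[Peak], GroundTruth]:
    """Emit (peaks, ground truth); identical spec + seed -> identical output."""
    rng = np.random.default_rng(spec.seed)
    rules = HeuristicRules()
    lo_mz, hi_mz = spec.mz_range

    exact_positions: list[float] = []  # every emitted exact m/z
    series_kmd: dict[int, list[float]] = {}  # z* -> kmd of accepted series
    used: set[MolecularFormula] = set()

    def separated(mz: float) -> bool:
        return all(abs(mz - q) / q * 1e6 >= spec.min_sep_ppm
                   for q in exact_positions)

    peaks: list[Peak] = []
    records: list[GroundTruthRecord] = []

    def emit(exact: float, intensity: float, rec_kind: str,
             formula: MolecularFormula | None, parent_index: int | None) -> int:
        observed = exact * (1.0 + rng.normal(0.0, spec.sigma_ppm) * 1e-6)
        peaks.append(Peak(mz=observed, intensity=float(intensity)))
        records.append(GroundTruthRecord(kind=rec_kind, formula=formula,
                                         parent_index=parent_index,
                                         exact_mz=exact))
        exact_positions.append(exact)
        return len(peaks) - 1

    accepted = 0
    attempts = 0
    max_attempts = max(200, spec.n_series * 60)
    while accepted < spec.n_series:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasibleSpec(
                f"could not place {spec.n_series} separated series in "
                f"m/z {lo_mz}-{hi_mz} after {attempts - 1} attempts")
        series = _draw_series(rng, spec, rules)
        if series is None or any(f in used for f in series):
            continue
        mzs = [ion_mz(f, spec.mode) for f in series]
        k0 = kendrick(mzs[0])
        if any(abs(k0.kmd - other) < spec.kmd_sep
               for other in series_kmd.get(k0.z_star, [])):
            continue
        sat_mzs = [mz + C13_C12_DELTA for mz in mzs] if spec.isotopologues else []
        if not all(separated(mz) for mz in mzs + sat_mzs):
            continue

        intensities = spec.intensity_median * rng.lognormal(
            0.0, spec.intensity_sigma, size=len(series))
        for f, mz, inten in zip(series, mzs, intensities):
            pi = emit(mz, inten, "parent", f, None)
            if spec.isotopologues:
                sat_i = f.c * 0.0107 * inten * max(
                    0.1, 1.0 + rng.normal(0.0, spec.iso_intensity_cv))
                emit(mz + C13_C12_DELTA, sat_i, "isotopologue", f, pi)
        used.update(series)
        series_kmd.setdefault(k0.z_star, []).append(k0.kmd)
        accepted += 1

    # unassignable noise: keep >= noise_reject_ppm from every candidate mass
    placed = 0
    tries = 0
    while placed < spec.n_noise_peaks:
        tries += 1
        if tries > spec.n_noise_peaks * 200:
            raise InfeasibleSpec("could not place unassignable noise peaks")
        nominal = int(rng.integers(int(lo_mz), int(hi_mz)))
        frac = float(rng.uniform(0.55, 0.95))
        mz = nominal + frac
        if not (lo_mz <= mz <= hi_mz) or not separated(mz):
            continue
        # widen the check so that after sigma_ppm perturbation the peak is
        # still > noise_reject_ppm/2 away from any lattice mass
        cands = generate_candidates(
            neutral_mass(mz, spec.mode), spec.noise_reject_ppm,
            spec.noise_check_ranges, rules, cap=100_000)
        if cands:
            continue
        inten = (spec.noise_intensity_factor * spec.intensity_median
                 * rng.lognormal(0.0, spec.intensity_sigma))
        emit(mz, inten, "noise", None, None)
        placed += 1

    # present the spectrum in m/z order, keeping truth aligned
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].mz)
    inv = {old: new for new, old in enumerate(order)}
    peaks_sorted = [peaks[i] for i in order]
    recs_sorted = [
        GroundTruthRecord(
            kind=r.kind, formula=r.formula,
            parent_index=None if r.parent_index is None else inv[r.parent_index],
            exact_mz=r.exact_mz)
        for r in (records[i] for i in order)
    ]
    return peaks_sorted, GroundTruth(records=recs_sorted)
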