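"""Readers and writers for centroid peak lists and assignment files.

The assignment interchange surface is three delimited text files —
monoisotopic assignments, isotopologue annotations, and the remaining
unassigned peaks — so results from any assignment software matching the
column schema (see docs/formats.md) can drive the report.  Masses are
printed with 7 decimals (sub-ppb at m/z 700), ppm errors with 3.

Peak lists are two-column (m/z, intensity) delimited text; the delimiter
is auto-detected among comma, tab and whitespace and a header row is
skipped if present.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .assigner import AssignedPeak, AssignmentSet, IsotopologueAnnotation
from .chem import MolecularFormula, Peak, ai_mod, dbe, kendrick
from .metrics import class_of

__all__ = [
    "PeakListFormatError",
    "read_peaklist",
    "write_assignment_set",
    "read_assignment_set",
    "export_data_table",
    "MONO_COLUMNS",
    "ISO_COLUMNS",
    "UNASSIGNED_COLUMNS",
]

logger = logging.getLogger(__name__)

MONO_COLUMNS = ["mz", "intensity", "formula", "calc_mz", "error_ppm",
                "C", "H", "N", "O", "S", "P",
                "dbe", "ai_mod", "hc", "oc", "class", "provenance"]
ISO_COLUMNS = ["mz", "intensity", "parent_mz", "parent_formula",
               "isotope", "ratio_obs_exp"]
UNASSIGNED_COLUMNS = ["mz", "intensity"]

#: Natural 13C abundance per carbon, duplicated from the assigner to avoid
#: an import cycle; kept equal by a unit test.
_C13_RATIO = 0.0107


class PeakListFormatError(ValueError):
    """A peak-list file could not be parsed; message carries line context."""


_SPLIT = re.compile(r"[,\t;]+|\s+")


def read_peaklist(path) -> list[Peak]:
    """Read a two-column (m/z, intensity) delimited text file.

    Comma-, tab- and whitespace-delimited files are all accepted; a header
    row is skipped.  Duplicate m/z values collapse to the maximum intensity
    with a warning.  Malformed data rows raise PeakListFormatError with
    line numbers.
    """
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise PeakListFormatError(f"cannot read {path}: {exc}") from exc

    rows: list[tuple[float, float]] = []
    bad: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f for f in _SPLIT.split(line) if f]
        if len(fields) < 2:
            bad.append(f"line {lineno}: expected 2 columns, got {len(fields)}")
            continue
        try:
            mz, intensity = float(fields[0]), float(fields[1])
        except ValueError:
            if lineno == 1 or (not rows and not bad):
                continue  # header row
            bad.append(f"line {lineno}: non-numeric values {fields[:2]}")
            continue
        if mz <= 0 or intensity < 0:
            bad.append(f"line {lineno}: invalid peak ({mz}, {intensity})")
            continue
        rows.append((mz, intensity))

    if bad:
        raise PeakListFormatError(f"{path}: " + "; ".join(bad))
    if not rows:
        raise PeakListFormatError(f"{path}: no data rows found")

    seen: dict[float, float] = {}
    order: list[float] = []
    dups = 0
    for mz, inten in rows:
        if mz in seen:
            dups += 1
            seen[mz] = max(seen[mz], inten)
        else:
            seen[mz] = inten
            order.append(mz)
    if dups:
        logger.warning("%s: collapsed %d duplicate m/z rows (kept max intensity)",
                       path, dups)
    return [Peak(mz=mz, intensity=seen[mz]) for mz in order]


def _fmt(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def write_assignment_set(aset: AssignmentSet, prefix) -> tuple[Path, Path, Path]:
    """Write the three-file convention: <prefix>_assigned.tsv,
    <prefix>_isotopologues.tsv, <prefix>_unassigned.tsv.

    Returns the three paths.  Empty parts produce header-only files.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    p_mono = prefix.parent / (prefix.name + "_assigned.tsv")
    p_iso = prefix.parent / (prefix.name + "_isotopologues.tsv")
    p_un = prefix.parent / (prefix.name + "_unassigned.tsv")

    mono_rows = []
    for a in aset.monoisotopic:
        f = a.formula
        mono_rows.append([
            _fmt(a.peak.mz, 7), f"{a.peak.intensity:.6g}", f.hill(),
            _fmt(a.calc_mz, 7), _fmt(a.error_ppm, 3),
            f.c, f.h, f.n, f.o, f.s, f.p,
            _fmt(a.dbe, 1), _fmt(a.ai_mod, 4), _fmt(a.hc, 4), _fmt(a.oc, 4),
            a.class_label, a.provenance])
    pd.DataFrame(mono_rows, columns=MONO_COLUMNS).to_csv(p_mono, sep="\t", index=False)

    iso_rows = []
    for iso in aset.isotopologues:
        iso_rows.append([
            _fmt(iso.peak.mz, 7), f"{iso.peak.intensity:.6g}",
            _fmt(iso.parent_mz, 7), iso.parent_formula.hill(), iso.label,
            _fmt(iso.observed_ratio / iso.expected_ratio, 4)])
    pd.DataFrame(iso_rows, columns=ISO_COLUMNS).to_csv(p_iso, sep="\t", index=False)

    un_rows = [[_fmt(p.mz, 7), f"{p.intensity:.6g}"] for p in aset.unassigned]
    pd.DataFrame(un_rows, columns=UNASSIGNED_COLUMNS).to_csv(p_un, sep="\t", index=False)
    return p_mono, p_iso, p_un


def _read_table(path: Path) -> pd.DataFrame:
    # sep=None + python engine sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python")


def read_assignment_set(prefix=None, *, mono_path=None, iso_path=None,
                        unassigned_path=None) -> AssignmentSet:
    """Read a three-file set written by this package or compatible software.

    Either pass a prefix (expects the write_assignment_set naming) or the
    three paths explicitly.  A missing isotopologue file is treated as
    empty, since external assignment software may not emit one.  Unknown
    extra columns are preserved in ``AssignmentSet.extra_columns``.
    """
    if prefix is not None:
        prefix = Path(prefix)
        mono_path = prefix.parent / (prefix.name + "_assigned.tsv")
        iso_path = prefix.parent / (prefix.name + "_isotopologues.tsv")
        unassigned_path = prefix.parent / (prefix.name + "_unassigned.tsv")
    if mono_path is None or unassigned_path is None:
        raise ValueError("need a prefix or explicit mono/unassigned paths")

    extras: dict[str, pd.DataFrame] = {}

    mono_df = _read_table(Path(mono_path))
    missing = [c for c in ("mz", "intensity", "formula") if c not in mono_df.columns]
    if missing:
        raise PeakListFormatError(f"{mono_path}: missing columns {missing}")
    extra_cols = [c for c in mono_df.columns if c not in MONO_COLUMNS]
    if extra_cols:
        extras["monoisotopic"] = mono_df[extra_cols]

    mono = []
    for row in mono_df.itertuples(index=False):
        f = MolecularFormula.parse(str(row.formula))
        calc = float(getattr(row, "calc_mz", row.mz))
        err = float(getattr(row, "error_ppm", 0.0))
        mono.append(AssignedPeak(
            peak=Peak(mz=float(row.mz), intensity=float(row.intensity)),
            formula=f, calc_mz=calc, error_ppm=err,
            provenance=str(getattr(row, "provenance", "seed")),
            dbe=dbe(f), ai_mod=ai_mod(f), hc=f.h / f.c, oc=f.o / f.c,
            class_label=class_of(f), kendrick=kendrick(float(row.mz))))

    isos: list[IsotopologueAnnotation] = []
    if iso_path is not None and Path(iso_path).exists():
        iso_df = _read_table(Path(iso_path))
        extra_cols = [c for c in iso_df.columns if c not in ISO_COLUMNS]
        if extra_cols:
            extras["isotopologues"] = iso_df[extra_cols]
        for row in iso_df.itertuples(index=False):
            pf = MolecularFormula.parse(str(row.parent_formula))
            expected = pf.c * _C13_RATIO
            isos.append(IsotopologueAnnotation(
                peak=Peak(mz=float(row.mz), intensity=float(row.intensity)),
                parent_mz=float(row.parent_mz), parent_formula=pf,
                label=str(row.isotope),
                observed_ratio=float(row.ratio_obs_exp) * expected,
                expected_ratio=expected))

    un_df = _read_table(Path(unassigned_path))
    unassigned = [Peak(mz=float(r.mz), intensity=float(r.intensity))
                  for r in un_df.itertuples(index=False)]

    aset = AssignmentSet(monoisotopic=mono, isotopologues=isos,
                         unassigned=unassigned)
    aset.extra_columns = extras or None  # opaque passthrough
    return aset


def export_data_table(report, path) -> Path:
    """Write the report's record table (one row per monoisotopic assignment)
    as tab-delimited text — the downloadable data-table contract."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.records.to_csv(path, sep="\t", index=False)
    return path
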