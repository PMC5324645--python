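"""Homologous-series grouping, seed-and-propagate assignment, isotopologues."""

import dataclasses

import pytest

from ivk.assigner import (
    AssignmentConfig,
    annotate_isotopologues,
    assign,
    group_series,
)
from ivk.chem import (
    C13_C12_DELTA,
    MolecularFormula,
    NEGATIVE_H,
    Peak,
    ion_mz,
)
from ivk.generator import ElementRanges, generate_candidates, passes_rules
from ivk.synth import MixtureSpec, make_mixture


def F(text):
    return MolecularFormula.parse(text)


def exact_peaks(formulas, intensity=100.0):
    return [Peak(mz=ion_mz(f, NEGATIVE_H), intensity=intensity) for f in formulas]


CFG = AssignmentConfig(ranges=ElementRanges(n=(0, 2), s=(0, 1)))


class TestGroupSeries:
    def test_exact_ch2_ladder_is_one_series(self):
        peaks = exact_peaks([F("C9H10O5"), F("C10H12O5"), F("C11H14O5")])
        series = group_series(peaks, CFG)
        assert len(series) == 1
        assert series[0].member_peak_indices == (0, 1, 2)

    def test_single_peak_is_singleton_series(self):
        series = group_series([Peak(mz=301.1, intensity=1.0)], CFG)
        assert len(series) == 1
        assert series[0].member_peak_indices == (0,)

    def test_disjoint_series_recovered_exactly(self):
        spec = MixtureSpec(n_series=10, sigma_ppm=0.0, isotopologues=False,
                           n_noise_peaks=0, seed=3)
        peaks, gt = make_mixture(spec)
        series = group_series(peaks, CFG)
        assert len(series) == 10
        # members of one series share one true O/N/S/DBE family
        for s in series:
            fams = {dataclasses.astuple(gt.records[i].formula)[2:]
                    for i in s.member_peak_indices}
            assert len(fams) == 1

    def test_members_share_z_star(self):
        spec = MixtureSpec(n_series=5, sigma_ppm=0.2, isotopologues=True,
                           n_noise_peaks=5, seed=4)
        peaks, _ = make_mixture(spec)
        from ivk.chem import kendrick
        for s in group_series(peaks, CFG):
            zs = {kendrick(peaks[i].mz).z_star for i in s.member_peak_indices}
            assert zs == {s.z_star}
            kmds = sorted(kendrick(peaks[i].mz).kmd for i in s.member_peak_indices)
            assert all(b - a <= CFG.kmd_tol for a, b in zip(kmds, kmds[1:]))


class TestAssign:
    def test_empty_input(self):
        aset = assign([], CFG)
        assert len(aset) == 0

    def test_exact_mass_peaks_fully_recovered(self):
        spec = MixtureSpec(n_series=12, sigma_ppm=0.0, isotopologues=False,
                           n_noise_peaks=0, seed=5)
        peaks, gt = make_mixture(spec)
        aset = assign(peaks, CFG)
        assert len(aset.monoisotopic) == len(peaks)
        by_mz = {a.peak.mz: a for a in aset.monoisotopic}
        for pk, rec in zip(peaks, gt.records):
            assert by_mz[pk.mz].formula == rec.formula
            assert by_mz[pk.mz].error_ppm == pytest.approx(0.0, abs=1e-6)

    def test_pure_noise_all_unassigned(self):
        spec = MixtureSpec(n_series=1, series_len=(5, 5), sigma_ppm=0.0,
                           isotopologues=False, n_noise_peaks=30, seed=6)
        peaks, gt = make_mixture(spec)
        noise = [p for p, r in zip(peaks, gt.records) if r.kind == "noise"]
        aset = assign(noise, CFG)
        assert not aset.monoisotopic and not aset.isotopologues
        assert len(aset.unassigned) == len(noise)

    def test_partition_property(self, srfa_mixture, srfa_assignment):
        peaks, _ = srfa_mixture
        aset = srfa_assignment
        assert (len(aset.monoisotopic) + len(aset.isotopologues)
                + len(aset.unassigned)) == len(peaks)
        mzs = ([a.peak.mz for a in aset.monoisotopic]
               + [i.peak.mz for i in aset.isotopologues]
               + [p.mz for p in aset.unassigned])
        assert sorted(mzs) == sorted(p.mz for p in peaks)

    def test_determinism(self):
        spec = MixtureSpec(n_series=8, sigma_ppm=0.2, isotopologues=True,
                           n_noise_peaks=10, seed=7)
        peaks, _ = make_mixture(spec)
        a1 = assign(peaks, CFG)
        a2 = assign(list(peaks), CFG)
        assert a1.monoisotopic == a2.monoisotopic
        assert a1.isotopologues == a2.isotopologues
        assert a1.unassigned == a2.unassigned

    def test_unique_candidate_oracle_agreement(self, srfa_mixture, srfa_assignment,
                                               srfa_config):
        """Any assigned peak whose member-tolerance candidate list has exactly
        one entry must carry exactly that formula."""
        cfg = srfa_config
        from ivk.chem import neutral_mass
        checked = 0
        for a in srfa_assignment.monoisotopic[:150]:
            cands = generate_candidates(
                neutral_mass(a.peak.mz, cfg.mode), cfg.tol_ppm_member,
                cfg.ranges, cfg.rules)
            if len(cands) == 1:
                assert a.formula == cands[0].formula
                checked += 1
        assert checked > 10

    def test_assigned_formulae_pass_all_rules(self, srfa_assignment, srfa_config):
        for a in srfa_assignment.monoisotopic:
            assert passes_rules(a.formula, srfa_config.rules)
            assert abs(a.error_ppm) <= srfa_config.tol_ppm_member

    def test_recovery_monotone_in_mass_error(self):
        def recovery(sigma):
            spec = MixtureSpec(n_series=15, sigma_ppm=sigma, isotopologues=False,
                               n_noise_peaks=0, seed=11)
            peaks, gt = make_mixture(spec)
            aset = assign(peaks, CFG)
            by_mz = {a.peak.mz: a.formula for a in aset.monoisotopic}
            hits = sum(1 for p, r in zip(peaks, gt.records)
                       if by_mz.get(p.mz) == r.formula)
            return hits / len(peaks)

        rates = [recovery(s) for s in (0.0, 0.3, 2.5)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))
        assert rates[0] == 1.0

    def test_min_rel_intensity_drops_grass_to_unassigned(self):
        spec = MixtureSpec(n_series=6, sigma_ppm=0.0, isotopologues=False,
                           n_noise_peaks=0, seed=13)
        peaks, _ = make_mixture(spec)
        strict = dataclasses.replace(CFG, min_rel_intensity=0.5)
        aset = assign(peaks, strict)
        base = max(p.intensity for p in peaks)
        for p in aset.unassigned:
            assert p.intensity < 0.5 * base
        assert len(aset) == len(peaks)


class TestIsotopologues:
    def _parent(self, formula, intensity=1000.0):
        pk = Peak(mz=ion_mz(formula, NEGATIVE_H), intensity=intensity)
        [ap] = assign([pk], CFG).monoisotopic
        return ap

    def test_in_band_satellite_annotated(self):
        f = F("C10H12O5")
        parent = self._parent(f)
        sat = Peak(mz=parent.peak.mz + C13_C12_DELTA,
                   intensity=0.107 * parent.peak.intensity)
        isos, rest = annotate_isotopologues([parent], [sat], CFG)
        assert len(isos) == 1 and not rest
        assert isos[0].parent_formula == f
        assert isos[0].label == "13C1"
        assert isos[0].expected_ratio == pytest.approx(10 * 0.0107)
        assert isos[0].observed_ratio == pytest.approx(0.107)

    def test_out_of_band_satellite_rejected(self):
        parent = self._parent(F("C10H12O5"))
        too_big = Peak(mz=parent.peak.mz + C13_C12_DELTA,
                       intensity=0.9 * parent.peak.intensity)  # > 3 x 0.107
        isos, rest = annotate_isotopologues([parent], [too_big], CFG)
        assert not isos and rest == [too_big]

    def test_no_satellite_within_window(self):
        parent = self._parent(F("C10H12O5"))
        far = Peak(mz=parent.peak.mz + C13_C12_DELTA + 0.01, intensity=100.0)
        isos, rest = annotate_isotopologues([parent], [far], CFG)
        assert not isos and rest == [far]

    def test_closest_parent_in_ppm_wins(self):
        p1 = self._parent(F("C10H12O5"), intensity=1000.0)
        sat_mz = p1.peak.mz + C13_C12_DELTA
        isos, _ = annotate_isotopologues([p1], [Peak(mz=sat_mz * (1 + 2e-7),
                                                     intensity=107.0)], CFG)
        assert len(isos) == 1 and isos[0].parent_mz == p1.peak.mz
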