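"""Report model, HTML contract, coverage overlay, static plots."""

import json

import pytest
from lxml import html as lxml_html

from ivk.assigner import AssignmentConfig, AssignmentSet, assign
from ivk.chem import (C13_C12_DELTA, MolecularFormula, NEGATIVE_H, Peak,
                      ai_mod, dbe, ion_mz)
from ivk.generator import ElementRanges
from ivk.report import (
    HOVER_FIELDS,
    build_report,
    build_report_model,
    batch_static_plots,
    chemspider_url,
    coverage_series,
)

CFG = AssignmentConfig(ranges=ElementRanges(n=(0, 2), s=(0, 1)))


@pytest.fixture(scope="module")
def small_set():
    formulas = [MolecularFormula.parse(t)
                for t in ("C9H10O5", "C10H12O5", "C11H14O5", "C14H18O7",
                          "C15H20O7")]
    peaks = [Peak(mz=ion_mz(f, NEGATIVE_H), intensity=50.0 * (i + 1))
             for i, f in enumerate(formulas)]
    peaks.append(Peak(mz=peaks[0].mz + C13_C12_DELTA, intensity=4.8))
    peaks.append(Peak(mz=peaks[3].mz + C13_C12_DELTA, intensity=30.0))
    peaks += [Peak(mz=333.3333, intensity=1.0), Peak(mz=444.4444, intensity=1.0),
              Peak(mz=555.5555, intensity=1.0)]
    aset = assign(peaks, CFG)
    assert (len(aset.monoisotopic), len(aset.isotopologues),
            len(aset.unassigned)) == (5, 2, 3)
    return aset


@pytest.fixture(scope="module")
def small_model(small_set):
    return build_report_model(small_set)


class TestChemspiderUrl:
    def test_contains_hill_formula(self):
        assert "C6H6" in chemspider_url(MolecularFormula.parse("C6H6"))

    def test_deterministic(self):
        f = MolecularFormula.parse("C9H10O5")
        assert chemspider_url(f) == chemspider_url(f)

    def test_all_six_elements_in_hill_order(self):
        f = MolecularFormula(c=2, h=5, n=1, o=2, s=1, p=1)
        assert "C2H5NO2PS" in chemspider_url(f)


class TestReportModel:
    def test_derived_fields_match_recomputation(self, small_set, small_model):
        for rec, a in zip(small_model.records.itertuples(), small_set.monoisotopic):
            f = MolecularFormula.parse(rec.formula)
            assert f == a.formula
            assert rec.dbe == dbe(f)
            assert rec.ai_mod == pytest.approx(ai_mod(f))
            assert rec.hc == pytest.approx(f.h / f.c)
            assert rec.oc == pytest.approx(f.o / f.c)

    def test_base_peak_has_unit_relative_intensity(self, small_model):
        assert small_model.records["rel_intensity"].max() == pytest.approx(1.0)

    def test_coverage_series_lengths_match_partition(self, small_set, small_model):
        series = coverage_series(small_model)
        assert len(series["monoisotopic"]) == len(small_set.monoisotopic)
        assert len(series["isotopologue"]) == len(small_set.isotopologues)
        assert len(series["unassigned"]) == len(small_set.unassigned)

    def test_all_assigned_coverage_has_empty_unassigned(self):
        peaks = [Peak(mz=ion_mz(MolecularFormula.parse("C9H10O5"), NEGATIVE_H),
                      intensity=5.0)]
        model = build_report_model(assign(peaks, CFG))
        assert coverage_series(model)["unassigned"] == []


def _payload_of(doc):
    stores = doc.xpath('//script[@id="ivk-data"]')
    assert len(stores) == 1, "exactly one embedded record store"
    return json.loads(stores[0].text)


class TestHtmlContract:
    def test_document_structure(self, small_model, tmp_path):
        path = build_report(small_model, tmp_path / "report.html")
        doc = lxml_html.fromstring(path.read_text(encoding="utf-8"))
        # three tab containers
        assert len(doc.xpath('//div[contains(@class,"ivk-tab")]')) == 3
        # four linked panels on tab 1, all reading the single store
        panels = doc.xpath('//div[@id="tab-main"]//svg[@class="ivk-panel"]')
        assert len(panels) == 4
        assert all(p.get("data-source") == "ivk-data" for p in panels)
        # self-contained: no external scripts, stylesheets or images
        assert not doc.xpath("//script[@src]")
        assert not doc.xpath("//link[@href]")
        assert not doc.xpath("//img[@src]")

    def test_embedded_records_complete(self, small_model, tmp_path):
        path = build_report(small_model, tmp_path / "report.html")
        data = _payload_of(lxml_html.fromstring(path.read_text(encoding="utf-8")))
        assert len(data["records"]) == len(small_model.records)
        assert data["hover_fields"] == HOVER_FIELDS
        for rec in data["records"]:
            for field in HOVER_FIELDS:
                assert field in rec
            assert rec["chemspider_url"].startswith("https://www.chemspider.com")
            assert rec["formula"] in rec["chemspider_url"]

    def test_embedded_values_equal_exported_table(self, small_model, tmp_path):
        import pandas as pd
        from ivk.io import export_data_table
        path = build_report(small_model, tmp_path / "report.html")
        data = _payload_of(lxml_html.fromstring(path.read_text(encoding="utf-8")))
        table = pd.read_csv(export_data_table(small_model, tmp_path / "t.tsv"),
                            sep="\t")
        for i, rec in enumerate(data["records"]):
            assert rec["formula"] == table.loc[i, "formula"]
            assert rec["mz"] == pytest.approx(table.loc[i, "mz"])
            assert rec["index"] == table.loc[i, "index"]

    def test_overlay_series_lengths_embedded(self, small_set, small_model, tmp_path):
        path = build_report(small_model, tmp_path / "report.html")
        data = _payload_of(lxml_html.fromstring(path.read_text(encoding="utf-8")))
        assert len(data["isotopologues"]) == len(small_set.isotopologues)
        assert len(data["unassigned"]) == len(small_set.unassigned)

    def test_empty_model_yields_valid_document_with_notice(self, tmp_path):
        model = build_report_model(AssignmentSet([], [], []))
        path = build_report(model, tmp_path / "empty.html")
        doc = lxml_html.fromstring(path.read_text(encoding="utf-8"))
        assert len(doc.xpath('//div[contains(@class,"ivk-tab")]')) == 3
        assert doc.xpath('//p[@class="notice"]')
        assert _payload_of(doc)["records"] == []


class TestStaticPlots:
    def test_two_panels_per_format(self, small_model, tmp_path):
        files = batch_static_plots(small_model, tmp_path, ("svg", "png"))
        assert len(files) == 4
        names = {p.name for p in files}
        assert names == {"van_krevelen.svg", "van_krevelen.png",
                         "dbe_vs_c.svg", "dbe_vs_c.png"}
        assert all(p.stat().st_size > 0 for p in files)

    def test_vector_output_is_byte_stable(self, small_model, tmp_path):
        a = batch_static_plots(small_model, tmp_path / "a", ("svg",))
        b = batch_static_plots(small_model, tmp_path / "b", ("svg",))
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_empty_model_still_renders_axes(self, tmp_path):
        model = build_report_model(AssignmentSet([], [], []))
        files = batch_static_plots(model, tmp_path, ("svg",))
        assert len(files) == 2 and all(p.stat().st_size > 0 for p in files)
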