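"""Standalone interactive HTML report and batch static plots.

The report is one self-contained HTML document with three tabs:

1. four linked panels — van Krevelen (H/C vs O/C, coloured by m/z),
   centroid mass spectrum, DBE vs carbon number and modified aromaticity
   index vs carbon number (both coloured by oxygen number) — with zoom,
   pan, hover and shift-drag box selection linked across all panels;
2. an assignment-coverage overlay: the centroid spectrum with
   monoisotopic, isotopologue and unassigned peaks as distinct series;
3. the full data table, selection-linked and downloadable as TSV.

All panels and the table read ONE embedded JSON record store, so linked
selection is index-based and cannot desynchronise.  Each glyph carries a
ChemSpider formula-search hyperlink (opened on click of a selected glyph);
no network access is needed to render the document.

Static publication-quality van Krevelen and DBE-vs-C# figures (SVG/PNG/PDF)
use matplotlib with the same visual encodings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from urllib.parse import quote

import pandas as pd

from .assigner import AssignmentSet
from .chem import MolecularFormula
from .metrics import glyph_size, vk_region

__all__ = [
    "ReportModel",
    "build_report_model",
    "build_report",
    "coverage_series",
    "chemspider_url",
    "batch_static_plots",
]

RECORD_COLUMNS = ["index", "mz", "intensity", "rel_intensity", "formula",
                  "c", "o", "hc", "oc", "dbe", "ai_mod", "error_ppm",
                  "class", "region", "chemspider_url"]

#: Fields shown by the hover tooltip, in display order.
HOVER_FIELDS = ["formula", "mz", "intensity", "error_ppm", "dbe", "ai_mod", "class"]


def chemspider_url(f: MolecularFormula) -> str:
    """Deterministic ChemSpider formula-search URL (Hill notation, encoded)."""
    return "https://www.chemspider.com/Search.aspx?q=" + quote(f.hill())


@dataclass
class ReportModel:
    """Plot-ready tables driving every report panel.

    ``records`` has one row per monoisotopic assignment (columns in
    RECORD_COLUMNS; ``index`` is the shared linked-selection key);
    ``isotopologues`` and ``unassigned`` are (mz, intensity) overlay series.
    """

    records: pd.DataFrame
    isotopologues: pd.DataFrame
    unassigned: pd.DataFrame


def build_report_model(aset: AssignmentSet) -> ReportModel:
    """Flatten an AssignmentSet into the plot-ready report model."""
    rows = []
    max_i = max((a.peak.intensity for a in aset.monoisotopic), default=0.0)
    for i, a in enumerate(aset.monoisotopic):
        rows.append({
            "index": i,
            "mz": a.peak.mz,
            "intensity": a.peak.intensity,
            "rel_intensity": a.peak.intensity / max_i if max_i > 0 else 0.0,
            "formula": a.formula.hill(),
            "c": a.formula.c,
            "o": a.formula.o,
            "hc": a.hc,
            "oc": a.oc,
            "dbe": a.dbe,
            "ai_mod": a.ai_mod,
            "error_ppm": a.error_ppm,
            "class": a.class_label,
            "region": vk_region(a.formula),
            "chemspider_url": chemspider_url(a.formula),
        })
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    isos = pd.DataFrame(
        [{"mz": x.peak.mz, "intensity": x.peak.intensity} for x in aset.isotopologues],
        columns=["mz", "intensity"])
    un = pd.DataFrame(
        [{"mz": p.mz, "intensity": p.intensity} for p in aset.unassigned],
        columns=["mz", "intensity"])
    return ReportModel(records=records, isotopologues=isos, unassigned=un)


def coverage_series(model: ReportModel) -> dict[str, list[tuple[float, float]]]:
    """The three coverage-overlay series (m/z, intensity) for tab 2.

    Series lengths equal the AssignmentSet partition sizes.
    """
    return {
        "monoisotopic": list(zip(model.records["mz"], model.records["intensity"])),
        "isotopologue": list(zip(model.isotopologues["mz"],
                                 model.isotopologues["intensity"])),
        "unassigned": list(zip(model.unassigned["mz"], model.unassigned["intensity"])),
    }


def _payload(model: ReportModel) -> str:
    data = {
        "records": model.records.to_dict(orient="records"),
        "isotopologues": model.isotopologues.to_dict(orient="records"),
        "unassigned": model.unassigned.to_dict(orient="records"),
        "hover_fields": HOVER_FIELDS,
    }
    return json.dumps(data, separators=(",", ":"))


def build_report(model: ReportModel, out_path, title: str = "i-van Krevelen report") -> Path:
    """Write the self-contained three-tab HTML report; returns the path."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    notice = "" if len(model.records) else \
        '<p class="notice">No assigned formulae in this dataset.</p>'
    html = (_TEMPLATE
            .replace("__TITLE__", title)
            .replace("__NOTICE__", notice)
            .replace("__DATA__", _payload(model)))
    out_path.write_text(html, encoding="utf-8")
    return out_path


def batch_static_plots(model: ReportModel, out_dir,
                       formats: tuple[str, ...] = ("svg", "png")) -> list[Path]:
    """Publication-quality van Krevelen and DBE-vs-C# figures.

    One file per (panel, format); vector output is byte-stable across runs
    for a fixed model.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    matplotlib.rcParams["svg.hashsalt"] = "ivk"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = model.records
    sizes = [glyph_size(v, 1.0, 4.0, 80.0) if len(df) else 0.0
             for v in df.get("rel_intensity", [])]

    panels = {
        "van_krevelen": dict(x="oc", y="hc", c="mz", cmap="viridis",
                             xlabel="O/C", ylabel="H/C", clabel="m/z"),
        "dbe_vs_c": dict(x="c", y="dbe", c="o", cmap="plasma",
                         xlabel="Carbon number", ylabel="DBE",
                         clabel="Oxygen number"),
    }
    out: list[Path] = []
    for name, cfgp in panels.items():
        fig, ax = plt.subplots(figsize=(5.0, 4.0), dpi=150)
        if len(df):
            sc = ax.scatter(df[cfgp["x"]], df[cfgp["y"]], s=sizes,
                            c=df[cfgp["c"]], cmap=cfgp["cmap"],
                            alpha=0.75, linewidths=0)
            fig.colorbar(sc, ax=ax, label=cfgp["clabel"])
        ax.set_xlabel(cfgp["xlabel"])
        ax.set_ylabel(cfgp["ylabel"])
        ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        for fmt in formats:
            p = out_dir / f"{name}.{fmt}"
            fig.savefig(p, format=fmt, metadata=_no_date_metadata(fmt))
            out.append(p)
        plt.close(fig)
    return out


def _no_date_metadata(fmt: str):
    # strip timestamps so vector output is reproducible byte-for-byte
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return None


_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>__TITLE__</title>
<style>
body { font-family: sans-serif; margin: 0.5em 1em; background: #fafafa; }
h1 { font-size: 1.2em; }
.tabbar button { padding: 0.4em 1.2em; border: 1px solid #888; background: #eee;
                 cursor: pointer; font-size: 1em; }
.tabbar button.active { background: #fff; border-bottom: 2px solid #fff; font-weight: bold; }
.ivk-tab { display: none; padding-top: 0.6em; }
.ivk-tab.visible { display: block; }
.grid { display: grid; grid-template-columns: 1fr 1fr; gap: 8px; }
.panelbox { background: #fff; border: 1px solid #ccc; position: relative; }
.panelbox h3 { margin: 2px 6px; font-size: 0.9em; font-weight: normal; color: #333; }
svg.ivk-panel { display: block; }
#tooltip { position: fixed; pointer-events: none; background: rgba(255,255,255,0.97);
           border: 1px solid #666; padding: 4px 6px; font-size: 0.78em; display: none;
           z-index: 10; white-space: pre; }
table.ivk-table { border-collapse: collapse; font-size: 0.8em; }
table.ivk-table th, table.ivk-table td { border: 1px solid #bbb; padding: 2px 6px; }
table.ivk-table tr.selected { background: #ffe9a8; }
table.ivk-table tr { cursor: pointer; }
.legend span { margin-right: 1.2em; font-size: 0.85em; }
.swatch { display: inline-block; width: 0.8em; height: 0.8em; margin-right: 0.3em; }
.hint { color: #555; font-size: 0.8em; }
.notice { color: #a00; }
</style>
</head>
<body>
<h1>__TITLE__</h1>
__NOTICE__
<div class="tabbar">
  <button id="btn-main" class="active">Linked plots</button>
  <button id="btn-coverage">Assignment coverage</button>
  <button id="btn-table">Data table</button>
</div>
<div class="ivk-tab visible" id="tab-main">
  <p class="hint">Drag = pan, wheel = zoom, double-click = reset,
     Shift+drag = box-select (linked across panels and table),
     click a selected point = open its ChemSpider formula search.</p>
  <div class="grid">
    <div class="panelbox"><h3>van Krevelen (colour: m/z)</h3>
      <svg id="panel-vk" class="ivk-panel" data-source="ivk-data"></svg></div>
    <div class="panelbox"><h3>Centroid mass spectrum</h3>
      <svg id="panel-spectrum" class="ivk-panel" data-source="ivk-data"></svg></div>
    <div class="panelbox"><h3>DBE vs carbon number (colour: O#)</h3>
      <svg id="panel-dbe" class="ivk-panel" data-source="ivk-data"></svg></div>
    <div class="panelbox"><h3>AI(mod) vs carbon number (colour: O#)</h3>
      <svg id="panel-aimod" class="ivk-panel" data-source="ivk-data"></svg></div>
  </div>
</div>
<div class="ivk-tab" id="tab-coverage">
  <p class="legend">
    <span><span class="swatch" style="background:#4477cc"></span>monoisotopic</span>
    <span><span class="swatch" style="background:#33a02c"></span>isotopologue</span>
    <span><span class="swatch" style="background:#e31a1c"></span>unassigned</span>
  </p>
  <div class="panelbox"><h3>Spectrum with assignment coverage</h3>
    <svg id="panel-coverage" class="ivk-panel" data-source="ivk-data"></svg></div>
</div>
<div class="ivk-tab" id="tab-table">
  <p><button id="download-tsv">Download table as TSV</button></p>
  <div style="max-height: 70vh; overflow: auto;">
    <table class="ivk-table" id="data-table"></table>
  </div>
</div>
<div id="tooltip"></div>
<script id="ivk-data" type="application/json">__DATA__</script>
<script>
"use strict";
var DATA = JSON.parse(document.getElementById("ivk-data").textContent);
var REC = DATA.records;
var selected = new Set();

/* ------- small viridis approximation ------- */
var VIRIDIS = [[68,1,84],[71,44,122],[59,81,139],[44,113,142],[33,144,141],
               [39,173,129],[92,200,99],[170,220,50],[253,231,37]];
function cmap(t) {
  if (!isFinite(t)) t = 0;
  t = Math.max(0, Math.min(1, t));
  var x = t * (VIRIDIS.length - 1), i = Math.floor(x), f = x - i;
  var a = VIRIDIS[i], b = VIRIDIS[Math.min(i + 1, VIRIDIS.length - 1)];
  function mix(k) { return Math.round(a[k] + (b[k] - a[k]) * f); }
  return "rgb(" + mix(0) + "," + mix(1) + "," + mix(2) + ")";
}
function extent(vals) {
  var lo = Infinity, hi = -Infinity;
  vals.forEach(function (v) { if (v < lo) lo = v; if (v > hi) hi = v; });
  if (!isFinite(lo)) { lo = 0; hi = 1; }
  if (lo === hi) { lo -= 0.5; hi += 0.5; }
  var pad = (hi - lo) * 0.05;
  return [lo - pad, hi + pad];
}
function niceTicks(lo, hi, n) {
  var span = hi - lo, step = Math.pow(10, Math.floor(Math.log10(span / n)));
  var err = span / n / step;
  if (err >= 7.5) step *= 10; else if (err >= 3.5) step *= 5; else if (err >= 1.5) step *= 2;
  var ticks = [], t = Math.ceil(lo / step) * step;
  for (; t <= hi + 1e-12; t += step) ticks.push(+t.toPrecision(10));
  return ticks;
}
function fmtNum(v) {
  if (typeof v !== "number") return String(v);
  if (Math.abs(v) >= 1e5) return v.toExponential(3);
  return (Math.round(v * 10000) / 10000).toString();
}

/* ------- panel machinery: zoom/pan/hover/box-select on one svg ------- */
var PANELS = [];
function makePanel(svgId, opts) {
  var svg = document.getElementById(svgId);
  var W = 460, H = 330, ML = 52, MR = 12, MT = 8, MB = 34;
  svg.setAttribute("width", W); svg.setAttribute("height", H);
  var panel = {
    svg: svg, opts: opts, W: W, H: H, ML: ML, MR: MR, MT: MT, MB: MB,
    x0: opts.xExtent[0], x1: opts.xExtent[1],
    y0: opts.yExtent[0], y1: opts.yExtent[1],
    home: opts.xExtent.concat(opts.yExtent)
  };
  panel.sx = function (v) { return ML + (v - panel.x0) / (panel.x1 - panel.x0) * (W - ML - MR); };
  panel.sy = function (v) { return H - MB - (v - panel.y0) / (panel.y1 - panel.y0) * (H - MT - MB); };
  panel.ix = function (px) { return panel.x0 + (px - ML) / (W - ML - MR) * (panel.x1 - panel.x0); };
  panel.iy = function (py) { return panel.y0 + (H - MB - py) / (H - MT - MB) * (panel.y1 - panel.y0); };
  attachInteraction(panel);
  PANELS.push(panel);
  return panel;
}
function svgEl(name, attrs) {
  var el = document.createElementNS("http://www.w3.org/2000/svg", name);
  for (var k in attrs) el.setAttribute(k, attrs[k]);
  return el;
}
function drawAxes(panel) {
  var s = panel.svg;
  s.appendChild(svgEl("rect", {x: panel.ML, y: panel.MT,
    width: panel.W - panel.ML - panel.MR, height: panel.H - panel.MT - panel.MB,
    fill: "none", stroke: "#999"}));
  niceTicks(panel.x0, panel.x1, 6).forEach(function (t) {
    var px = panel.sx(t);
    if (px < panel.ML - 0.5 || px > panel.W - panel.MR + 0.5) return;
    s.appendChild(svgEl("line", {x1: px, y1: panel.H - panel.MB,
      x2: px, y2: panel.H - panel.MB + 4, stroke: "#333"}));
    var lab = svgEl("text", {x: px, y: panel.H - panel.MB + 15,
      "text-anchor": "middle", "font-size": "9"});
    lab.textContent = fmtNum(t); s.appendChild(lab);
  });
  niceTicks(panel.y0, panel.y1, 6).forEach(function (t) {
    var py = panel.sy(t);
    if (py < panel.MT - 0.5 || py > panel.H - panel.MB + 0.5) return;
    s.appendChild(svgEl("line", {x1: panel.ML - 4, y1: py, x2: panel.ML, y2: py,
      stroke: "#333"}));
    var lab = svgEl("text", {x: panel.ML - 6, y: py + 3,
      "text-anchor": "end", "font-size": "9"});
    lab.textContent = fmtNum(t); s.appendChild(lab);
  });
  var xl = svgEl("text", {x: (panel.ML + panel.W - panel.MR) / 2,
    y: panel.H - 4, "text-anchor": "middle", "font-size": "10"});
  xl.textContent = panel.opts.xLabel; s.appendChild(xl);
  var yl = svgEl("text", {x: 11, y: (panel.MT + panel.H - panel.MB) / 2,
    "text-anchor": "middle", "font-size": "10",
    transform: "rotate(-90 11 " + (panel.MT + panel.H - panel.MB) / 2 + ")"});
  yl.textContent = panel.opts.yLabel; s.appendChild(yl);
}
function inView(panel, x, y) {
  return x >= panel.x0 && x <= panel.x1 && y >= panel.y0 && y <= panel.y1;
}
function renderPanel(panel) {
  var s = panel.svg;
  while (s.firstChild) s.removeChild(s.firstChild);
  drawAxes(panel);
  var o = panel.opts, hasSel = selected.size > 0;
  if (o.kind === "scatter") {
    REC.forEach(function (r) {
      var x = r[o.xField], y = r[o.yField];
      if (!inView(panel, x, y)) return;
      var isSel = selected.has(r.index);
      var el = svgEl("circle", {
        cx: panel.sx(x), cy: panel.sy(y),
        r: 2 + 6 * Math.sqrt(r.rel_intensity),
        fill: cmap((r[o.cField] - o.cExtent[0]) / (o.cExtent[1] - o.cExtent[0] || 1)),
        stroke: isSel ? "#000" : "none", "stroke-width": isSel ? 1.5 : 0,
        opacity: hasSel && !isSel ? 0.15 : 0.8
      });
      el.dataset.index = r.index;
      s.appendChild(el);
    });
  } else if (o.kind === "spectrum") {
    o.series.forEach(function (ser) {
      ser.data.forEach(function (d, j) {
        if (d.mz < panel.x0 || d.mz > panel.x1) return;
        var isSel = ser.linked && selected.has(d.index);
        var el = svgEl("line", {
          x1: panel.sx(d.mz), x2: panel.sx(d.mz),
          y1: panel.sy(Math.max(0, panel.y0)), y2: panel.sy(Math.min(d.intensity, panel.y1)),
          stroke: isSel ? "#ff8800" : ser.color,
          "stroke-width": isSel ? 2 : 1,
          opacity: hasSel && ser.linked && !isSel ? 0.18 : 0.85
        });
        if (ser.linked) el.dataset.index = d.index;
        s.appendChild(el);
      });
    });
  }
}
function renderAll() {
  PANELS.forEach(renderPanel);
  renderTable();
}

/* ------- interactions ------- */
var tooltip = document.getElementById("tooltip");
function attachInteraction(panel) {
  var svg = panel.svg, drag = null;
  svg.addEventListener("mousedown", function (ev) {
    drag = {x: ev.offsetX, y: ev.offsetY, box: ev.shiftKey,
            x0: panel.x0, x1: panel.x1, y0: panel.y0, y1: panel.y1, moved: false};
    ev.preventDefault();
  });
  svg.addEventListener("mousemove", function (ev) {
    if (drag) {
      drag.moved = true;
      if (drag.box) {
        var old = svg.querySelector(".selrect");
        if (old) old.remove();
        svg.appendChild(svgEl("rect", {class: "selrect",
          x: Math.min(drag.x, ev.offsetX), y: Math.min(drag.y, ev.offsetY),
          width: Math.abs(ev.offsetX - drag.x), height: Math.abs(ev.offsetY - drag.y),
          fill: "rgba(80,120,255,0.15)", stroke: "#4466cc"}));
      } else {
        var dx = panel.ix(ev.offsetX) - panel.ix(drag.x);
        var dy = panel.iy(ev.offsetY) - panel.iy(drag.y);
        panel.x0 = drag.x0 - dx; panel.x1 = drag.x1 - dx;
        panel.y0 = drag.y0 - dy; panel.y1 = drag.y1 - dy;
        renderPanel(panel);
      }
      return;
    }
    showHover(panel, ev);
  });
  window.addEventListener("mouseup", function (ev) {
    if (!drag) return;
    if (drag.box) {
      var r = svg.querySelector(".selrect");
      if (r) r.remove();
      applyBoxSelect(panel, drag.x, drag.y, ev.clientX - svg.getBoundingClientRect().left,
                     ev.clientY - svg.getBoundingClientRect().top);
    }
    drag = null;
  });
  svg.addEventListener("wheel", function (ev) {
    ev.preventDefault();
    var f = ev.deltaY > 0 ? 1.15 : 1 / 1.15;
    var cx = panel.ix(ev.offsetX), cy = panel.iy(ev.offsetY);
    panel.x0 = cx - (cx - panel.x0) * f; panel.x1 = cx + (panel.x1 - cx) * f;
    panel.y0 = cy - (cy - panel.y0) * f; panel.y1 = cy + (panel.y1 - cy) * f;
    renderPanel(panel);
  });
  svg.addEventListener("dblclick", function () {
    panel.x0 = panel.home[0]; panel.x1 = panel.home[1];
    panel.y0 = panel.home[2]; panel.y1 = panel.home[3];
    renderPanel(panel);
  });
  svg.addEventListener("mouseleave", function () { tooltip.style.display = "none"; });
  svg.addEventListener("click", function (ev) {
    if (drag && drag.moved) return;
    var t = ev.target;
    if (t.dataset && t.dataset.index !== undefined) {
      var idx = +t.dataset.index;
      if (selected.has(idx)) {
        var rec = REC[idx];
        if (rec && rec.chemspider_url) window.open(rec.chemspider_url, "_blank");
      }
    }
  });
}
function recAt(panel, px, py) {
  var o = panel.opts, best = null, bestD = 10;
  if (o.kind === "scatter") {
    REC.forEach(function (r) {
      var d = Math.hypot(panel.sx(r[o.xField]) - px, panel.sy(r[o.yField]) - py);
      if (d < bestD) { bestD = d; best = r; }
    });
  } else {
    REC.forEach(function (r) {
      var d = Math.abs(panel.sx(r.mz) - px);
      if (d < 4 && py > panel.sy(r.intensity) - 4 && d < bestD) { bestD = d; best = r; }
    });
  }
  return best;
}
function showHover(panel, ev) {
  var r = recAt(panel, ev.offsetX, ev.offsetY);
  if (!r) { tooltip.style.display = "none"; return; }
  tooltip.textContent = DATA.hover_fields.map(function (f) {
    return f + ": " + fmtNum(r[f]);
  }).join("\\n");
  tooltip.style.display = "block";
  tooltip.style.left = (ev.clientX + 12) + "px";
  tooltip.style.top = (ev.clientY + 12) + "px";
}
function applyBoxSelect(panel, px0, py0, px1, py1) {
  var o = panel.opts;
  var xa = Math.min(panel.ix(px0), panel.ix(px1)), xb = Math.max(panel.ix(px0), panel.ix(px1));
  var ya = Math.min(panel.iy(py0), panel.iy(py1)), yb = Math.max(panel.iy(py0), panel.iy(py1));
  selected = new Set();
  REC.forEach(function (r) {
    var x, y;
    if (o.kind === "scatter") { x = r[o.xField]; y = r[o.yField]; }
    else { x = r.mz; y = r.intensity / 2; }
    if (x >= xa && x <= xb && ((o.kind === "scatter" && y >= ya && y <= yb) ||
        (o.kind === "spectrum" && r.intensity >= ya))) selected.add(r.index);
  });
  renderAll();
}

/* ------- data table ------- */
var TABLE_COLS = ["index","mz","intensity","rel_intensity","formula","c","o",
                  "hc","oc","dbe","ai_mod","error_ppm","class","region"];
function renderTable() {
  var tbl = document.getElementById("data-table");
  tbl.innerHTML = "";
  var hr = document.createElement("tr");
  TABLE_COLS.forEach(function (cname) {
    var th = document.createElement("th"); th.textContent = cname; hr.appendChild(th);
  });
  tbl.appendChild(hr);
  REC.forEach(function (r) {
    var tr = document.createElement("tr");
    if (selected.has(r.index)) tr.className = "selected";
    TABLE_COLS.forEach(function (cname) {
      var td = document.createElement("td");
      td.textContent = fmtNum(r[cname]);
      tr.appendChild(td);
    });
    tr.addEventListener("click", function () {
      if (selected.has(r.index)) selected.delete(r.index); else selected.add(r.index);
      renderAll();
    });
    tbl.appendChild(tr);
  });
}
document.getElementById("download-tsv").addEventListener("click", function () {
  var lines = [TABLE_COLS.concat(["chemspider_url"]).join("\\t")];
  REC.forEach(function (r) {
    lines.push(TABLE_COLS.concat(["chemspider_url"]).map(function (cname) {
      return r[cname];
    }).join("\\t"));
  });
  var blob = new Blob([lines.join("\\n")], {type: "text/tab-separated-values"});
  var a = document.createElement("a");
  a.href = URL.createObjectURL(blob);
  a.download = "ivk_data_table.tsv";
  a.click();
});

/* ------- tabs ------- */
[["btn-main", "tab-main"], ["btn-coverage", "tab-coverage"],
 ["btn-table", "tab-table"]].forEach(function (pair) {
  document.getElementById(pair[0]).addEventListener("click", function () {
    document.querySelectorAll(".ivk-tab").forEach(function (el) {
      el.classList.remove("visible");
    });
    document.querySelectorAll(".tabbar button").forEach(function (el) {
      el.classList.remove("active");
    });
    document.getElementById(pair[1]).classList.add("visible");
    this.classList.add("active");
  });
});

/* ------- build panels ------- */
function col(field) { return REC.map(function (r) { return r[field]; }); }
var allMz = col("mz").concat(DATA.isotopologues.map(function (d) { return d.mz; }),
                             DATA.unassigned.map(function (d) { return d.mz; }));
var allInt = col("intensity").concat(
  DATA.isotopologues.map(function (d) { return d.intensity; }),
  DATA.unassigned.map(function (d) { return d.intensity; }));
makePanel("panel-vk", {kind: "scatter", xField: "oc", yField: "hc", cField: "mz",
  xExtent: extent(col("oc")), yExtent: extent(col("hc")), cExtent: extent(col("mz")),
  xLabel: "O/C", yLabel: "H/C"});
makePanel("panel-spectrum", {kind: "spectrum",
  series: [{color: "#4477cc", linked: true,
            data: REC.map(function (r) { return {mz: r.mz, intensity: r.intensity, index: r.index}; })}],
  xExtent: extent(col("mz")), yExtent: [0, extent(col("intensity"))[1]],
  xLabel: "m/z", yLabel: "intensity"});
makePanel("panel-dbe", {kind: "scatter", xField: "c", yField: "dbe", cField: "o",
  xExtent: extent(col("c")), yExtent: extent(col("dbe")), cExtent: extent(col("o")),
  xLabel: "Carbon number", yLabel: "DBE"});
makePanel("panel-aimod", {kind: "scatter", xField: "c", yField: "ai_mod", cField: "o",
  xExtent: extent(col("c")), yExtent: extent(col("ai_mod")), cExtent: extent(col("o")),
  xLabel: "Carbon number", yLabel: "AI(mod)"});
makePanel("panel-coverage", {kind: "spectrum",
  series: [
    {color: "#4477cc", linked: true,
     data: REC.map(function (r) { return {mz: r.mz, intensity: r.intensity, index: r.index}; })},
    {color: "#33a02c", linked: false, data: DATA.isotopologues},
    {color: "#e31a1c", linked: false, data: DATA.unassigned}
  ],
  xExtent: extent(allMz), yExtent: [0, extent(allInt)[1]],
  xLabel: "m/z", yLabel: "intensity"});
renderAll();
</script>
</body>
</html>
"""
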