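# ivk — formula assignment and interactive van Krevelen reports

`ivk` assigns molecular formulae to centroid peak lists from
high-resolution mass spectrometry of complex mixtures (natural organic
matter, petroleum, beverages …) and renders the results as a standalone,
fully interactive HTML report. It targets the standard petroleomics
workflow: ultra-accurate masses → candidate formulae → Kendrick
homologous-series assignment → van Krevelen / DBE / aromaticity-index
visualisation.

Core quantities, for a neutral formula C_cH_hN_nO_oS_sP_p:

- **DBE** = 1 + c − h/2 + n/2 + p/2
- **AI_mod** = (1 + c − o/2 − s − h/2) / (c − o/2 − s − n − p), clamped
  to 0 in degenerate cases
- **Kendrick mass** KM = m/z × 14 / m(CH₂); **KMD** = round(KM) − KM;
  **z\*** = (round(m/z) mod 14) − 14 — members of a CH₂ homologous series
  share KMD and z\*, which is what the assigner exploits: each series is
  seeded from its least ambiguous member (exhaustive rule-filtered
  candidate generation at 0.5 ppm) and the seed formula is propagated
  ±CH₂ along the series at 1 ppm.

The result is the three-part partition used by all downstream tools:
monoisotopic assignments, ¹³C₁ isotopologue annotations, and unassigned
peaks — written as three delimited text files (schema in
[docs/formats.md](docs/formats.md)), so data assigned by any other
software can drive the report too.

## Worked example

Generate a synthetic fulvic-acid-like spectrum with known ground truth,
assign it, and build the report:

```
$ ivk synth --series 10 --sigma-ppm 0.2 --noise 20 --seed 42 \
      --out peaks.csv --truth truth.tsv
170 peaks -> peaks.csv
truth -> truth.tsv

$ ivk assign peaks.csv --mode neg --elements C1-100H0-200N0-2O0-30S0-1 \
      --out demo
assigned 75, isotopologues 75, unassigned 20
demo_assigned.tsv
demo_isotopologues.tsv
demo_unassigned.tsv
```

The mixture contained 10 CH₂-homologous series (75 monoisotopic peaks),
each with a ¹³C₁ satellite, plus 20 unassignable noise peaks; the
assigner recovers the partition exactly. The first assignment rows:

```
mz           intensity  formula    calc_mz      error_ppm  ...  dbe  ai_mod  class  provenance
241.0870823  943214     C15H14O3   241.0870178  0.267      ...  9.0  0.5556  O3     propagated
255.1026565  363536     C16H16O3   255.1026679  -0.045     ...  9.0  0.5172  O3     propagated
```

`error_ppm` is the signed mass error of the observed peak against the
calculated [M−H]⁻ m/z; `provenance` records whether the formula came from
the series seed or from ±CH₂ propagation.

```
$ ivk classes demo_assigned.tsv --out classes.tsv
10 classes -> classes.tsv       # heteroatom class, count, intensity share

$ ivk plot demo --out report.html
report.html
```

`report.html` is self-contained: tab 1 shows the four linked panels
(van Krevelen, centroid spectrum, DBE vs C#, AI_mod vs C#) with zoom,
pan, hover and box selection linked across all panels; tab 2 overlays
monoisotopic (blue), isotopologue (green) and unassigned (red) peaks on
one spectrum; tab 3 is the selection-linked, downloadable data table.
Clicking a selected point opens a ChemSpider search for its formula.

The formula generator doubles as a threshold-picking tool:

```
$ ivk generate --mass 122.0367794 --ppm 1 --elements C1-20H0-40O0-10 --spacing
formula  calc_mass    error_ppm
C7H6O2   122.0367794  -0.000
# minimum spacing: n/a (fewer than 2 candidates)
```

One candidate within 1 ppm — the assignment is unambiguous at this mass
and tolerance.

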