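# File formats

All interchange files are delimited text. The package writes tab-separated
files; readers also accept comma-separated files with the same columns.
Masses (m/z) are printed with 7 decimal places (sub-ppb at m/z 700), ppm
errors with 3, derived ratios with 4.

## Peak list (input)

Two columns, `(m/z, intensity)`, delimiter auto-detected among comma, tab
and whitespace; an optional header row is skipped; lines starting with `#`
are ignored. Duplicate m/z rows are collapsed to the maximum intensity
(with a warning). Malformed rows abort the parse with their line numbers.

```
mz,intensity
241.0870823,943214
255.1026565,363536
```

## Three-file assignment set

Written by `write_assignment_set(aset, prefix)` as
`<prefix>_assigned.tsv`, `<prefix>_isotopologues.tsv`,
`<prefix>_unassigned.tsv`. The three files partition the input peak list.

### `<prefix>_assigned.tsv` — monoisotopic assignments

| column | meaning |
|---|---|
| `mz` | observed m/z, Th |
| `intensity` | centroid intensity, arbitrary units |
| `formula` | neutral formula, Hill notation (`C9H10O5`) |
| `calc_mz` | calculated ion m/z for the formula |
| `error_ppm` | signed (observed − calc)/calc × 10⁶ |
| `C H N O S P` | element counts of the neutral formula |
| `dbe` | double bond equivalents |
| `ai_mod` | modified aromaticity index |
| `hc`, `oc` | H/C and O/C ratios |
| `class` | heteroatom class label (`O5`, `N1O3`, `CH`) |
| `provenance` | `seed` or `propagated` (how the series assigner reached it) |

### `<prefix>_isotopologues.tsv`

| column | meaning |
|---|---|
| `mz`, `intensity` | the satellite peak |
| `parent_mz` | observed m/z of the monoisotopic parent |
| `parent_formula` | Hill formula of the parent |
| `isotope` | isotopologue label, e.g. `13C1` |
| `ratio_obs_exp` | observed/expected intensity ratio (expected = C# × 0.0107 × parent intensity) |

### `<prefix>_unassigned.tsv`

`mz`, `intensity` only.

Readers tolerate a missing isotopologue file (treated as empty, for
interoperability with assignment software that emits none) and preserve
unknown extra columns as opaque annotations
(`AssignmentSet.extra_columns`).

## Data-table export

`export_data_table(model, path)` writes one row per monoisotopic
assignment with the report's full column set:

```
index mz intensity rel_intensity formula c o hc oc dbe ai_mod error_ppm class region chemspider_url
```

This is byte-for-byte the same record set embedded in the HTML report.
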