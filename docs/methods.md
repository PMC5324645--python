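# Methods

## Problem setting

Ultra-high-resolution mass spectrometry (FTICR) of complex mixtures such
as dissolved natural organic matter yields thousands of resolvable
centroid peaks between roughly m/z 200 and 700, with mass accuracy at the
ppb–ppm level. At that accuracy each peak can be attributed to a neutral
molecular formula C_cH_hN_nO_oS_sP_p, and the collection of formulae is
then read through standard petroleomics summaries: the van Krevelen
diagram (H/C vs O/C), double bond equivalents vs carbon number, the
modified aromaticity index vs carbon number, and heteroatom class
distributions. This package implements the full chain — formula
generation, homologous-series assignment, isotopologue annotation,
three-file text interchange, and a linked interactive HTML report — plus a
synthetic-spectrum generator with known ground truth that all integration
tests run against.

## Exact-mass chemistry

Monoisotopic masses use an isotope table pinned inside the package
(¹H 1.0078250319, ¹²C 12, ¹⁴N 14.0030740052, ¹⁶O 15.9949146221,
³²S 31.97207069, ³¹P 30.97376151 Da) so results are bit-stable across
environments. Ion conversion for [M−H]⁻/[M+H]⁺ uses the proton mass
1.0072765 Da — i.e. the electron mass is accounted for, which matters at
the claimed sub-ppm accuracy (the electron is ~4.5 ppb at m/z 121).

Derived metrics:

- DBE = 1 + C − H/2 + N/2 + P/2 (O and S do not contribute). Half-integer
  values flag chemically impossible even-electron neutrals and are
  filtered by the generator rules.
- AI_mod = (1 + C − O/2 − S − H/2) / (C − O/2 − S − N − P), the
  conservative aromaticity estimate that treats half the oxygen as
  carbonyl-like. Degenerate cases (denominator ≤ 0 or numerator < 0)
  clamp to 0 rather than NaN so the plots stay total functions.
- Kendrick coordinates use the CH₂ base: KM = m/z × 14 / 14.0156500638,
  nominal KM = round-half-up(KM), KMD = nominal − KM (positive for typical
  CHO ions; this is the dominant petroleomics sign convention), and
  z* = (round-half-up(m/z) mod 14) − 14. Members of one CH₂ homologous
  series share KMD exactly and share z* as long as their mass defects do
  not cross a half-integer (at which point the nominal mass increments by
  15 instead of 14 — the well-known z* wrap; peaks past a wrap simply
  start a new series and are seeded independently).

## Candidate-formula generation

`generate_candidates` enumerates every formula inside configurable element
ranges (defaults C 1–100, H 0–200, N 0–5, O 0–30, S 0–2, P 0–0) whose
mass lies within a ppm window of the target and which passes a set of
heuristic plausibility rules standard for natural-organic-matter work:

- valence cap H ≤ 2C + 2 + N + P,
- H/C ∈ [0.3, 3.0], O/C ≤ 1.2, N/C ≤ 0.5, S/C ≤ 0.2,
- DBE a non-negative integer (the even-electron parity condition for
  neutral molecules).

Every rule is individually toggleable. The search iterates heteroatoms in
the outer loops and solves the feasible hydrogen-count interval
analytically from the mass window; the test suite verifies output
equivalence (membership and order) with a naive full nested-loop search
on randomized draws. Candidates are ordered by |ppm error|, then fewer
heteroatoms, fewer oxygens, Hill string. A configurable cap (default
10 000) guards against pathological windows.

`min_candidate_spacing` reports the smallest mass gap between any two
surviving candidates near an m/z — the quantity an analyst uses to decide
how tight an assignment tolerance must be before it is unambiguous.

## Homologous-series assignment

Peaks are stratified by z* and single-linkage clustered on KMD (link
threshold `kmd_tol`, default 0.0005 — an order of magnitude above the KMD
jitter produced by 0.2 ppm mass error at m/z 500, and far below typical
inter-series KMD spacing). Within each series:

1. **Seeding.** Every member gets a candidate list at the tight seed
   tolerance (default 0.5 ppm). The seed is the member with the fewest
   candidates (least ambiguous), ties broken by intensity; its best
   candidate becomes the seed formula.
2. **Propagation.** Every other member is offered seed ± k·CH₂ (k from
   the m/z difference) and accepted only if the propagated formula
   reproduces its m/z within the member tolerance (default 1.0 ppm) and
   passes every heuristic rule.

Single-linkage clustering can merge two genuine series whose KMDs happen
to fall within the link threshold; the minority family then fails the
propagation check. The assigner therefore repeats the group-seed-propagate
pass on the still-unassigned remainder until a fixpoint (bounded by
`max_passes`); the first pass is the canonical algorithm, later passes
apply it unchanged to what is left. The procedure is deterministic; when
a peak is reachable from two series, the smaller |ppm error| wins (then
fewer heteroatoms, then Hill order).

After series assignment, the remaining peaks are searched for ¹³C₁
isotopologue satellites of the assigned peaks: a match requires the mass
offset +1.0033548 Da within the member tolerance AND an intensity inside
[0.2, 3.0] × (C# × 0.0107 × parent intensity). The band is deliberately
loose because centroid intensities of weak satellites are noisy; it is
configurable. Each leftover joins at most one parent (closest in ppm).
Doubly-substituted species (two ¹³C, one ¹⁸O) are not searched and
legitimately remain unassigned. The three parts — monoisotopic,
isotopologue, unassigned — always partition the input peak list.

**Choosing element ranges.** Ranges should reflect the chemistry expected
in the sample. This matters more than it may appear: with maximally wide
ranges (N ≤ 5 and S ≤ 2 simultaneously) the CHNOS lattice contains a
systematic near-coincidence (−6C +3H +5N +2S −4O ≈ +1.00335 Da, ~0.04 ppm
from the ¹³C−¹²C offset), so every ¹³C satellite of a CHO compound
acquires a spurious N₅S₂ candidate inside any ppm-scale tolerance and
satellite ladders get mis-seeded as monoisotopic. With ranges matched to
CHO/CHNO/CHOS classes (N ≤ 2, S ≤ 1) the nearest interferent to a
satellite position is ≥ 0.85 ppm away and the workflow is clean. The
bundled workflows for the SRFA-like synthetic mixture therefore assign
with N ≤ 2, S ≤ 1.

## Synthetic mixtures and what passing tests show

`make_mixture` emulates a negative-mode SRFA-like spectrum: 50 (default)
CH₂-homologous series of 5–12 members drawn from CHO/CHNO/CHOS classes
(weights 0.6/0.25/0.15, O 3–14, DBE 2–12) across m/z 200–700, log-normal
intensities (σ = 1.2 — a few dominant peaks over dense low-abundance
"grass"), Gaussian mass error (default σ = 0.2 ppm, typical of a
well-calibrated FTICR), ¹³C₁ satellites at C# × 1.07 % of the parent
intensity (±5 % noise), and 100 noise peaks placed in the 0.55–0.95
mass-defect band and verified (by running the generator at 2 ppm over the
widest ranges) to be unassignable.

Three fixture-design constraints keep the ground truth unambiguous:
emitted exact positions are ≥ 2.5 ppm apart; series in one z* stratum are
≥ 3 × `kmd_tol` apart in KMD; and series are kept clear of the
half-integer mass-defect wrap. Real spectra honour none of these
guarantees — peaks coalesce, series interleave at sub-threshold KMD
distances, and isobaric interferences exist — so the measured 100 %
recovery characterises the algorithm under resolvable conditions, not
instrument reality. What the integration tests do establish: the
partition property, determinism, correct seed/propagation logic, correct
isotopologue gating, and graceful degradation as mass error grows
(recovery is monotone non-increasing in σ).

Problem sizes used by the test suite and the acceptance script (50 series,
~430 parent peaks, ~960 total peaks; 100 randomized generator draws
against the brute-force oracle over a C ≤ 15 lattice) run in seconds while
exercising every code path; they are the package's reference conditions.

## Report

The HTML report is a single self-contained document (no external fetches;
~5 MB per 10⁴ records): three tabs — four linked panels, the coverage
overlay, the data table — all rendered by embedded vanilla JavaScript
from ONE JSON record store (`<script id="ivk-data">`). Linked selection
is index-based (shift-drag box select; selection highlights the same
records in every panel and the table), hover shows formula, m/z,
intensity, ppm error, DBE, AI_mod and class, wheel/drag zoom and pan,
double-click resets, and clicking a selected glyph opens that record's
ChemSpider formula-search URL (the only network action, and only on
click). Glyph area scales with the square root of relative abundance
(perceptually area-linear; configurable to linear in the static plots'
`glyph_size`). Colour encodes m/z on the van Krevelen panel and oxygen
number on the DBE and AI_mod panels.

Static publication plots (van Krevelen, DBE vs C#) are rendered with
matplotlib; SVG output is byte-stable across runs (fixed hash salt, no
timestamp metadata).

Van Krevelen compound-class regions are half-open boxes in (O/C, H/C),
first match wins: lipid-like [0, 0.2) × [1.7, 2.3), carbohydrate-like
[0.7, 1.3) × [1.7, 2.3), condensed-aromatic-like [0, 0.2) × [0.2, 1.0).
The classic anchors are approximate by nature; the boxes are configurable
and anything outside them is "unclassified".

## Known limitations

- Singly charged [M−H]⁻/[M+H]⁺ ions only; no multiply charged species,
  other adducts, or isotope fine structure.
- Elements limited to C, H, N, O, S, P; no halogens.
- No m/z recalibration: the assigner trusts the input axis.
- Only ¹³C₁ satellites are annotated; ¹³C₂/¹⁸O peaks stay unassigned.
- The series seeder prefers the least ambiguous member; in very dense
  lattices (wide ranges at high m/z) every member can be ambiguous and a
  series may seed on a wrong candidate, misassigning the whole ladder.
  The `min_candidate_spacing` utility is the recommended way to choose
  tolerances and ranges that avoid this regime.
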