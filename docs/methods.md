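# Methods

## The profiling model

The pipeline treats an LC-MS run as a map: scan index (a proxy for
retention time) against m/z, with centroid intensity as the third
dimension. Binning this map into fixed 50-scan × 1-Th compartments and
totaling intensities turns each run into a 48,000-dimensional feature
vector without any peak picking, alignment or noise filtering — every
ion signal, noise included, enters the matrix. The discovery unit (a
"factor") is one grid cell ranked by its loading on the first principal
component of the per-batch sample set; the biological claim the pipeline
supports is therefore deliberately coarse: *this 1-Th × 85-second window
of the spectral map rises or falls characteristically with fermentation
time*. Everything sharper than that (exact mass, charge, formula) is
recovered afterwards from the centroids inside the winning cells.

Key conventions, chosen once and used throughout:

- **Bins are half-open** on both axes (`[lo, hi)`), so labels like
  `455-456|1250-1300` tile the map without overlap, and an ion at
  exactly m/z 455.0 or scan 1300 has a unique home.
- **Scan index, not retention time**, defines the chromatographic axis;
  the scan → time map is linear over the 30–115 min acquisition window
  (3,000 scans ≈ 1.7 s each).
- **Cation masses subtract the electron mass** (H⁺ = 1.007276 Da,
  Na⁺ = 22.989220 Da). This is what makes the sodiated phthalate dimer
  come out at 803.5432 rather than the 803.5438 a neutral-atom sum
  gives, and what reproduces the deconvolution 358.271 → 357.264.
- **Reported masses are rounded half-to-even** at the conventional
  precisions (4 dp for neutral monoisotopic masses, 3 dp for
  deconvolved masses).

One published composition deserves a note: tables in circulation give
306.1962 Da for C17H26N2O3, but the monoisotopic mass of that formula is
306.1943 Da (the 1.9 mDa gap matches no isotope or adduct arithmetic).
The package reports 306.1943 and does not force agreement. Similarly, an
"exact m/z 445.322" sometimes printed for the 455–456 factor is treated
as a typo for 455.322, which deconvolutes to the accompanying 454.315.

## Normalization and PCA

Global median normalization rescales each sample by
`reference_median / sample_median`, with medians computed **only over
features positive in every sample** — otherwise presence/absence of
sparse features, not intensity, would drive the factors. The reference
is the first sample's median; the choice only fixes a global constant
and cancels in loadings ranking. The normalization needs a dense common
feature background to estimate loading from; on data where almost every
cell is empty in some sample the common-positive set collapses and the
factors become meaningless (the generator's baseline density is chosen
to keep roughly half the cells common-positive).

PCA is feature-centered and unscaled: per-feature autoscaling would
erase exactly the intensity information the loading rank is meant to
capture. Loadings are reported on a "PC score" scale,
`u_j · s_j / √(n−1)`, whose magnitudes track the intensity swing of the
feature; ranking (the operative quantity) is invariant to this scale.
Each component's sign is fixed so its largest-|loading| feature loads
positively, making "top 20 by signed PC1 loading" well defined. Ties in
loading value break by feature identifier. Zero-variance features are
retained with loading 0 rather than dropped.

The cross-batch intersection matches factors by identical feature id;
with `merge_adjacent` set, same-m/z factors in contiguous scan bins are
first coalesced into spans (an elution straddling a bin boundary is one
molecule, not two) and matched by span overlap.

## Annotation

Per factor: the apex is the maximum-intensity centroid in the cell
(ties to lower m/z); charge is inferred from an isotopologue companion
at `1.003355/z` above the apex (1–120 % of apex intensity, within
10 ppm, in the apex scan ± 1). Charges are tried **from the largest
down**: a z-charged envelope also shows peaks at whole multiples of its
spacing, so a smallest-first rule would claim a +2 ion with a visible
M+2 (one full Th up) as +1. An isolated peak defaults to z = 1 and is
flagged undetermined.

Neutral masses are computed under three adduct hypotheses — [M+H]⁺,
[M+Na]⁺, [2M+Na]⁺ — and all are searched; hypotheses are ranked by
their best candidate's |ppm error| with [M+H]⁺ winning ties. Formula
enumeration runs at 10 ppm over bounded element counts (default C ≤ 40,
H ≤ 80, N ≤ 6, O ≤ 10); peptide-composition enumeration at 5 ppm over
the 19 mass-distinct residues with Leu/Ile collapsed to `[L/I]`
(113.08406 Da; peptide mass = Σ residues + 18.010565). The tolerances
reflect orbitrap-class accuracy at R = 100,000; no RDBE/valence filter
is applied by default, since exact mass alone cannot justify one.
Masses above 1000 Da are not searched — formula assignment is too
redundant there — and are reported "N.A.". Factors that are
isotopologues of one molecule (scan bins overlapping, apexes an integer
number of spacings apart) are grouped by union-find, the lowest-m/z
member representing the group.

Background flagging is configuration, not chemistry: the default list
holds the two diisooctyl phthalate signatures (391.2843 and 803.5432
± 0.01 Th, eluting after 100 min), the plasticizer bleed every
reversed-phase LC system shows.

## Quantification

Extracted ion chromatograms are ±0.01-Th windows summed per scan
(window width is not stated by any convention; ±0.01 Th cleanly
separates the monoisotopic line from its M+1 at orbitrap accuracy).
Areas are trapezoidal integrals over retention time — area, not apex
height, because area is robust to scan-phase jitter. Relative series
multiply each run's area by that sample's global-median normalization
factor before scaling to the series maximum: raw areas confound the
compound's trajectory with injection/matrix loading, and the
normalization factors are exactly the pipeline's estimate of that
loading. Absolute quantification inverts an ordinary least-squares
calibration line (not forced through zero); values outside the
standards' concentration range are flagged extrapolated.

## The synthetic scenario

The generator emulates the study design so the pipeline can be tested
against known truth: 2 batches sampled on days (6, 11, 16, 21, 26, 34)
and (1, 5, 11, 19, 26, 34) after the start of the main fermentation,
2 technical replicates each (same abundances, different noise draws) —
24 runs of 3,000 scans.

Ground-truth compounds and their defaults:

| component | value | why |
|---|---|---|
| six rising compounds | four Leu/Ile peptides + C19H28O + C17H26N2O3, apexes 64.2–70.1 min | the characteristic fermentation compounds, at their reported elution times |
| trajectory | `A·(0.01 + 0.99·d²/(d²+8²))` | early-rising, half-max near day 8, day-34/day-1 ratio ≈ 37 |
| peak abundances A | 0.6–1.2 × 10⁶ (arb. units) | well above decoys/baseline; within ~2× of each other |
| phthalate | C24H38O4, constant, [M+H]⁺ + 0.4 × [2M+Na]⁺, apex 103.8 min, σ 0.5 min | instrument background, exempt from sample loading |
| decoys | 50, flat trajectories, log-normal levels ~1.5 × 10⁵, random CHNO formulas | realistic competition for top-20 slots |
| sample loading | `1.25 − 0.015·day` | mash matrix thins as fermentation proceeds; applied to sample signal and chemical baseline, not to the phthalate |
| elution | Gaussian, σ 0.15–0.5 min, truncated at 0.1 % of line apex | keeps peak lists compact; < 0.03 % area loss |
| isotope envelope | aggregated by nominal shift, depth 3 (¹³C 1.07 %, ¹⁵N 0.368 %, ²H 0.0115 %, ¹⁷O 0.038 %, ¹⁸O 0.205 %, ³³S/³⁴S) | all that 1-Th binning and spacing-based charge inference can see |
| noise | log-normal intensity CV 5 %, m/z jitter 1 ppm (1σ), baseline 60 peaks/scan, exponential intensities (scale 10³) | replicate-level scatter typical of a stable nanoLC-orbitrap setup |

The loading factor is the mechanism that places the *constant*
phthalate among the top PC1 factors, as observed in practice: median
normalization divides the declining loading out of sample-derived
features and thereby imprints its rising inverse on the instrument
background.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: chromatographic tailing and drift
(elution is symmetric-Gaussian, perfectly aligned across runs), ion
suppression and saturation, fine isotope structure, centroiding
artifacts of profile data, MS/MS fragmentation, and real biological
between-batch variation (both batches share one trajectory family; only
sampling days and noise differ). Retention-time disambiguation of Leu
vs Ile, which needs synthetic standards, is out of scope; candidates
stay at composition level.

## Numerical choices and degenerate inputs

- Binning totals use `numpy.bincount` in double precision; intensity
  conservation holds to ~1e-12 relative on realistic run sizes.
- Formula/peptide enumeration is depth-first over elements (residues)
  in descending mass with remaining-mass pruning; result sets are
  order-independent and verified against exhaustive lattice search.
- Candidate masses are recomputed from the composition, not accumulated,
  so reported ppm errors carry no summation drift.
- PCA requests for more components than samples allow truncate with a
  warning; fewer than 2 samples is an error. Empty factor cells,
  all-zero XIC series, inverted windows, singular calibration designs
  and non-dividing grid widths all raise immediately with named causes.
- Run CSVs write floats at `%.17g` and parse with round-trip float
  precision, so write → read is bit-identical.
- Seeding: every run derives its stream from (noise seed, batch, day,
  replicate), so runs are independent, reproducible, and insensitive to
  generation order.

## Problem sizes

The default study (24 runs × ~190k peaks, 48,000-cell grid, two
12-sample PCAs) executes end to end in a few seconds on one CPU; the
test suite exercises it once and reuses the result. Conservation and
search-oracle checks run on 100 seeded runs / 100 random targets.
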