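# Methods

This note documents the models behind each module, the defaults that
matter, the design choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate about real data.

## The assay being modeled

A steatosis high-content screen images two channels per field: a nuclear
stain from which valid cells are counted, and a neutral-lipid stain in which
triglyceride-filled lipid droplets appear as small bright cytoplasmic spots.
Each 384-well plate carries two full control columns — a stimulator control
(lipid induction at maximum, column 11 by default) and a neutral control (no
induction, column 12). Compound wells are normalized between the two control
means, hits are called by thresholds on inhibition and on viability, and
hits are confirmed by retest and dose–response. Control placement is
config-driven throughout (`PlateLayout`), never hard-coded, since layouts
differ between sites.

## Synthetic data generator

The generator is the package's ground-truth instrument. Design goals, in
order: (i) exactness — noiseless outputs must be *exactly* recoverable so
the analysis chain can be held to zero-error checks; (ii) statistical
honesty — summary-level and image-level plate simulation share the same
generative means; (iii) reproducibility — every generator is a pure
function of (parameters, seed).

- **Nuclei** are rendered as Gaussian-tapered disks: a flat core of the
  nominal radius (8–12 px at 20× scale) with a `exp(−((d−r)/τ)²/2)` skirt
  (τ = 1.5 px). This produces soft edges that genuinely exercise
  thresholding and the shape/size validity filters.
- **Droplets** are uniform-intensity hard disks (radius 2 px, 250–350 AU
  above background) whose centers are snapped to the pixel grid, so each
  droplet contributes exactly `area × intensity` of signal and every
  droplet of a given radius covers the same number of pixels. This is what
  makes exact noiseless recovery a well-posed requirement, and it keeps the
  image-level per-cell mean equal to the summary-mode closed form.
- **Placement.** Droplets live in an annulus around their owner nucleus
  (inner clearance 4 px beyond the nucleus edge, outer margin inside the
  ring width), are kept ≥ 2·r + 3 px from every other droplet field-wide so
  no two distinct droplets can merge during detection, and are required to
  be strictly nearest to their owner so ring assignment is unambiguous.
  Candidate positions that cannot be placed after 500 attempts are skipped
  (practically never at default densities); fields that exceed a packing
  fraction limit raise an error naming the limit.
- **Droplet-count coupling.** Each cell draws `max_droplets` (12) candidate
  droplets and includes candidate *i* iff `u_i < s`, where `s` is the
  steatosis level. Consequences: the expected count is exactly
  `s · max_droplets`, and for a fixed seed the droplet set grows
  monotonically with `s`, so ground-truth signal is monotone in the
  steatosis level by construction.
- **Plate modes.** Summary mode draws per-well aggregates directly:
  the well mean ISS is `s · max_droplets · area · intensity` with
  `s = s_min + (1 − inhibition)(1 − s_min)` (residual neutral staining
  `s_min` = 0.03), multiplied by unit-mean log-normal noise
  (`σ² = ln(1 + CV²)`, so the mean is exact and the SD is exactly
  `mean · CV`). Default CVs: 8% on ISS and spot count, 5% on cell count —
  chosen to land plate Z' in the 0.6–0.8 range typical of a robust
  lipid-accumulation assay. Image mode renders fields at the same means;
  a 36-plate campaign in summary mode runs in seconds, image mode is meant
  for small problems.
- **Noise model.** Additive Gaussian per channel, with an optional Poisson
  shot-noise flag (off by default so the zero-noise contracts hold
  bitwise). The generator does not model optics (PSF, vignetting), well
  edge effects (only a median-polish hook exists downstream), focus
  failures, or debris — passing recovery tests here shows the *analysis*
  is correct and calibrated, not that it is robust to every real-world
  artifact.
- **Fields per well** defaults to 6 and is configurable; acquisition
  protocols vary between 6 and 8 and nothing downstream depends on the
  choice.

## Imaging

Nuclei: Gaussian smoothing (σ = 2 px) → Otsu global threshold (or a fixed
absolute threshold) → connected components → distance-transform watershed
seeded by peak maxima ≥ 7 px apart to split touching nuclei. A constant
(blank or saturated) raster returns an empty result with a warning rather
than an error, since blank wells are routine. Roundness is
`4π·area/perimeter²` with the Crofton perimeter, clipped at 1.0 because
discretization overshoots on small disks. Validity defaults (area ≥ 150 px²,
roundness ≥ 0.5, border exclusion on) are package defaults tuned to the
generator's geometry; real screens must calibrate them to their cell line
and magnification.

Ring regions: a cytoplasm pixel belongs to nucleus L iff it lies outside
all nuclei, within the ring width of L's mask, and L is the nearest nucleus
by Euclidean distance, ties to the lower label. The implementation runs a
local exact EDT per nucleus in increasing label order with
strict-improvement updates, which reproduces the brute-force per-pixel
oracle bit-for-bit (ties included) at a cost linear in nucleus count times
window area rather than image area squared.

Spots: detection runs on a white top-hat (structuring disk radius 4 ≈ the
largest droplet) thresholded at median + 4·(1.4826·MAD) of the cytoplasm
pixels; both statistics are relative, so scaling the channel by c > 0
scales every integrated intensity by exactly c without changing the
detection mask. Spot intensity is the raw channel minus the cytoplasm
median background summed over spot pixels. Spots whose centroids lie
closer than 2 px (center-to-center Euclidean distance — the merge metric
had to be chosen, as building-block documentation rarely defines it) are
merged by single linkage into one spot with union pixels and summed
intensity. Spot ownership is the majority cytoplasm label over the spot's
pixels, ties to the lower label.

## Plate statistics

Z' uses |μ_s − μ_n| in the denominator; without the absolute value the sign
of the statistic would depend on the arbitrary order of the two groups.
The robust variant substitutes medians and 1.4826·MAD — the conventional
consistency factor for Gaussian data — because "robust Z'" has no single
canonical definition. %CV is 100·SD/mean per control group. Hit calling is
purely threshold-based (no multiple-testing correction — deliberately, as
single-point screens are triaged by effect size, not p-value): by default a
hit needs both ISS and spot-count inhibition ≥ 50% (the stricter of the two
published conventions; `require_spot_inhibition=False` relaxes to
ISS-only) and > 60% relative cell count; ≤ 40% relative cell count is
cytotoxic and wins over any inhibition. The relative cell count is measured
against the mean of both control columns. An optional per-row/column
median-polish toggle (off by default) stands in for proprietary
edge-effect corrections; full spatial-bias modeling (B-score) is out of
scope.

## Dose–response

The 4PL is fitted by bounded trust-region least squares on
(top, bottom, log10 IC50, hill) with a deterministic start: asymptotes from
the response extremes, IC50 from the tested concentration whose mean
response is nearest half-maximum, hill sign from the log-concentration
trend. IC50 is bounded within [min conc/100, max conc·100]. Replicates are
fitted jointly and unweighted by default. Constant responses and optimizer
failures return a fit flagged `converged=False` instead of raising, because
flat viability curves are the *expected* outcome for non-cytotoxic
compounds. A fitted IC50 above the highest tested concentration is reported
as right-censored ("> max tested") — the data cannot place the inflection,
and reporting a point estimate there would be spurious precision. Censored
viability potencies enter the selectivity ratio as conservative lower
bounds. Both the 10-point half-log and the 6-point (10 → 0.625 µM) layouts
are provided; neither is privileged.

## Compound profiling

Ward agglomeration is implemented directly via the Lance–Williams update on
squared dissimilarities with a fixed tie-break (lexicographically smallest
cluster-id pair among minimal merges) so linkages are reproducible to the
bit; tests verify equality against an independent centroid-formula oracle
and against scipy on tie-free data. Heights are merge dissimilarities (two
singletons at distance d merge at height d) and are monotone because Ward
is reducible. The caveat is stated rather than hidden: Ward's objective is
derived for Euclidean geometry and is applied to Tanimoto distances by
field convention. Tanimoto distance of two all-zero fingerprints is defined
as 0 (identical absence of features). Repeated pXC50 measurements are
aggregated median-within-source then max-across-sources — the median
absorbs replicate scatter inside one assay while the maximum preserves the
strongest annotated activity, the usual library-annotation convention; a
pure-median mode is available. The 7.0 cutoff marks the conventional
boundary of potent drug-like activity and only masks the matrix view; the
underlying values are retained.

## Expression

ΔCq subtracts the arithmetic mean Cq of the reference genes (HPRT1, GAPDH
by default) within each sample — averaging on the Cq scale is the standard
choice when no combination rule is specified — making fold changes immune
to per-sample offsets (plate effects). Amplification efficiency is fixed at
the classic value 2. Group comparisons: two-sample t-test for two groups,
one-way ANOVA with Tukey's post hoc for three or more, on the ΔCq scale.
The DEG filter keeps genes with fold change ≥ t or ≤ 1/t (t = 3 by
default) and p < 0.05; it is monotone in both thresholds and idempotent.
`venn3` is plain set arithmetic over gene ids; it consumes externally
produced DEG lists and implies nothing about how they were made.

## Pipeline

`run_screen` executes simulate → QC → call → retest → dose-response →
cluster → profile from one strictly-validated config with one global seed;
every stage failure names the stage and partial outputs are kept. Planted
actives carry a latent hill-1 IC50 (log-uniform 0.1–2 µM) from which both
their single-point screen inhibition and their retest/dose-response
behavior derive, so the same compound is consistent across stages. The
confirmation rule operationalizes "active at both concentrations" as
≥ 50% inhibition in at least 2/3 of high-dose replicates plus a declared
20% floor on mean low-dose inhibition — the floor is a config choice, not
an inferred constant. Manifests echo the full config and checksum every
output; identical configs reproduce identical checksums.

## Problem sizes in tests

The test suite and acceptance script run on deliberately small instances —
256–384 px fields with 8–20 cells, single plates in summary mode, 20–100
seeded replicates per recovery rate — sizes at which every oracle
(brute-force ring assignment, exhaustive greedy Ward, flood-fill counting,
closed-form plate moments) is exactly computable. The statistical
conclusions (recovery rates, Z' agreement) are properties of the estimators
and transfer to full-scale data; the wall-clock behavior of a 36-plate
image-level campaign does not, and image-level simulation at that scale is
intentionally out of the default path.

## Known limitations

- The nucleus segmenter is a parameter-light stand-in for proprietary
  building blocks; it assumes roughly convex, moderately separated nuclei
  and will under-split dense clumps.
- No illumination correction, PSF modeling, or 3-D imaging.
- Hit thresholds and validity criteria ship as declared defaults, not
  values inferred from any particular screen.
- The synthetic compound families are bit-vector constructs; they test the
  clustering machinery, not chemical realism of ECFP4 space.
- Batch-to-batch normalization across screening campaigns is out of scope;
  controls are per-plate by design.
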