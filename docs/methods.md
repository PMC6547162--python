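# Methods

`meioquant` re-implements, as a tested library, the quantification
procedures used in live-cell assays of meiosis-I chromosome
segregation in budding yeast, together with the ChIP and proteomics
quantifications that accompany such studies. This note records the
models, conventions and numerical choices, and what the synthetic-data
generator does and does not emulate.

## Live-cell spot quantification (`spots`)

Movies are 5-D stacks (frame, z, channel, y, x) with a pixel size in
um/px and a frame interval in minutes. The detection workflow mirrors
the ImageJ-style dot-counting plugins used for this assay:

1. **Z-projection.** Each channel is collapsed to 2-D. The projection
   type is maximum-intensity by default — standard for punctate
   kinetochore foci, which appear in one or two of the ~7 focal planes
   — with mean projection available behind a flag.
2. **Yen autothreshold.** The histogram uses 256 equal-width bins over
   `[min, max]` (the 8-bit ImageJ convention generalized to arbitrary
   dynamic range). For a split after bin *t* with background mass
   `P1`, background/foreground squared-probability masses `P1sq`,
   `P2sq`, the maximum-correlation criterion is
   `TC(t) = 2 ln(P1 (1 - P1)) - ln(P1sq * P2sq)`; splits leaving
   either side empty are excluded. Ties take the smallest threshold;
   the returned value is the upper edge of the background-side bin and
   **foreground is strictly greater than the threshold**. A constant
   image has no threshold and raises. The implementation is verified
   exactly against a brute-force scan of the criterion over every
   candidate split.
3. **Spot extraction.** Foreground components (8-connectivity) within
   the user's ROI become records with intensity-weighted sub-pixel
   centroid, pixel-count area, and mean detection-channel intensity.
   Records are ordered by descending mean intensity, ties by (y, x);
   downstream classification consumes the two brightest (kinetochore
   clusters are the brightest foci), the rest are retained.
4. **Cross-channel readout.** The second channel's mean is computed
   over *exactly* the detected pixel set, so both channels share one
   footprint by construction.

Intensity-weighted (rather than binary) centroids were chosen because
they are sub-pixel accurate on symmetric spots; on noise-free planted
Gaussians the centroid error is well below 0.5 px.

A practical note on thresholding sparse spots: when foci occupy a tiny
fraction of the field, the Yen threshold settles just above the
background mode, so the faint overlapping tails of two foci closer
than ~7 sigma bridge into a single component. Detection completeness
on closely spaced planted spots is therefore demonstrated with an
explicit threshold at half the planted peak (spot extraction accepts
either an automatic or a user-supplied threshold, as the original
interactive workflow did).

## Line profiles (`profiles`)

Where pericentromeric cohesin lies *between* bioriented kinetochores,
its signal is read along the segment joining the two kinetochore
centroids. Samples are evenly spaced at approximately unit-pixel
intervals (`ceil(L) + 1` samples including both endpoints: exactly
1 px for integer lengths, slightly finer otherwise, keeping the sample
set symmetric under endpoint reversal), interpolated bilinearly, and
taken at identical coordinates in every channel. The sampling density
of the original plugin is not documented; unit spacing is the chosen
convention and is configurable through the endpoints used.

Peak extraction returns the two brightest local maxima: strictly
greater than both neighbors, plateaus take their leftmost index, and
boundary samples count only when strictly greater than their single
neighbor (this keeps monotone profiles well-defined without inventing
edge peaks). If fewer than two local maxima exist the global maximum
is reported twice with a degeneracy flag rather than fabricating a
second peak.

## Phenotype classification (`classify`)

Scoring is anchored on anaphase-I onset: the first frame where the
marker (Cdc14 release or Pds1/securin disappearance) is on. The
scoring window is the **two frames strictly after onset** by default;
the alternative convention (onset frame plus the next) is selectable,
since the original wording — "within two time points after" — admits
both readings.

* **Heterozygous assay.** The maximum distance between the two
  brightest foci inside the window, in um. No second focus (or a
  distance below `split_min = 0.4` um, about 3–4 px at the stated
  magnification — the point at which two foci stop being visually
  distinct) → `co_segregated`; below 2.0 um → `split_proximal`
  (monoorientation lost, cohesion intact); at or above 2.0 um →
  `split_distal` (both lost). The proximal class is defined as
  strictly "< 2 um", so a distance of exactly 2.0 um is distal.
  Raising the boundary can only move cells distal → proximal.
* **Homozygous assay.** Foci carry spindle-pole assignments, either
  from the simulator or from a nearest-pole heuristic with a capture
  radius. Opposite poles → `segregating`; one pole →
  `co_segregating`; no poleward movement → `failing_to_segregate`.
* **Presence time course.** A frame is marker-positive when at least
  one focus exceeds `presence_factor` (default 2.0) times the
  background — a configurable stand-in for by-eye scoring, whose
  threshold is otherwise unknowable. The window is 4 h after onset
  (16 frames at 15-min intervals); truncation by the movie end is
  flagged.
* **Intensity normalization.** Values are divided by the arithmetic
  mean of a background cohort (by convention, 50 wild-type meiosis-II
  cells). The anaphase intensity readout averages the readout-channel
  signal of the brightest focus over the scoring window and then
  normalizes.
* **Population summaries** report per-replicate category fractions
  with across-replicate mean and SEM (sd/sqrt(n), ddof = 1; null for a
  single replicate).

Foci are linked across frames by greedy nearest-neighbor matching with
a maximum step of 1.5 um/frame — sufficient for a sparse two-focus
problem; no general tracker is attempted.

## ChIP quantification (`chip`)

* **qPCR.** `dCT = CT_ChIP - (CT_Input - log_E(dilution))` and
  enrichment `= E^-dCT`, with `E` the primer efficiency in (1, 2].
  "log_E" is the logarithm with base `E`: with dilution 1 the
  correction vanishes, the only dimensionally consistent reading. The
  CT entering the formula is the geometric mean of technical-replicate
  CTs, computed on the CT values directly as stated by the procedure.
  Enrichment is strictly decreasing in CT_ChIP and increasing in
  CT_Input.
* **Replicate aggregation.** Mean and SEM across biological
  replicates; a two-tailed paired t-test between conditions (>= 3
  pairs). Zero-variance paired differences make the statistic
  undefined; the result is flagged degenerate instead of reporting a
  fabricated p-value.
* **Spike-in calibration.** `OR = (Wc * IPx) / (Wx * IPc)` from reads
  mapped to the calibration (c) and experimental (x) genomes; OR is
  invariant under uniform count scaling, and every per-position value
  is multiplied by OR (ratios between positions are preserved
  exactly). Read alignment and counting are upstream and out of
  scope; counts enter as four positive numbers.
* **Composite profiles.** For offsets −3000..+3000 bp around each
  centromere midpoint (the BED interval midpoint; centromeres are
  unstranded), the raw median across centromeres is taken per offset;
  offsets falling off a chromosome end are excluded for that
  centromere with the contributing count recorded. No smoothing is
  applied by default (the original pipeline's choice is not
  documented; raw median keeps the estimator order-statistic exact).
  Profile differences are elementwise, null where either side lacks
  data. Coordinates are 0-based half-open on disk (bedGraph/BED).

## Per-residue peptide aggregation (`phospho`)

Phosphopeptides (enrichment eluate) and nonphosphopeptides
(flow-through) are processed as two independent aggregations. For each
(condition, replicate) a normalization factor is the ratio of summed
reference-protein (Smc3) peptide intensities to the baseline
condition's sum in the same replicate — per-replicate rather than
global, since IP efficiency varies per sample; multiplying all
intensities of one sample by any constant therefore leaves every ratio
unchanged. Each residue's value is the sum of normalized intensities
of *all* observed peptides whose span contains it (variable
modification forms and mis-cleaved peptides are distinct records that
all contribute). Per-replicate ratios are
`log2(condition) - log2(baseline)`; missing intensities are excluded
rather than zero-imputed (zero would poison the logarithm, and
missingness-model imputation belongs to interactor-level analysis,
which is out of scope). Replicate ratios are averaged and tested
against zero with a two-sided one-sample t-test (significant at
p < 0.05; zero-variance sets flagged degenerate, n = 1 yields a mean
with no test). On a residue covered by exactly one peptide the mean
ratio equals that peptide's normalized log2 ratio exactly.

Western-blot quantification is the double ratio
`(target_strain / target_wt) / (loading_strain / loading_wt)`.

## Synthetic data (`synth`)

The generator produces every input with recorded ground truth.
Defaults are the study conditions: 0.107 um/px, 15-min frames, 7
z-slices at 0.85 um, anaphase onset uniform on frames [3, 7) of a
10-frame movie, split probability 0.3 with proximal distances
N(1.0, 0.2) um and distal N(3.5, 0.5) um. Spots are rendered as
symmetric 2-D Gaussians (sigma 1.5 px) on each z-slice, attenuated in
z by a 1-D Gaussian — cheap and sufficient for projection-based
detection. Noise is Poisson on the scaled signal plus additive
Gaussian (camera characteristics are not stated anywhere
authoritative; Poisson scale 1.0 and read noise sd 5 AU are
conventional values and fully configurable), applied after rendering.
The anaphase marker is generated as a per-frame boolean, not an image,
because it serves only as an onset anchor. CT tables invert the
enrichment formula (so zero-jitter tables round-trip exactly);
coverage tracks are background plus a parametric peak at each
centromere plus Gaussian noise, with noiseless truth retained; peptide
tables assign each peptide the fold change `2^mean(planted log2 fc
over its span)` so single-coverage residues with constant planted fc
are recovered exactly.

What the generator does **not** emulate: photobleaching, stage drift,
whole-cell segmentation, focus shape asymmetry, read-level sequencing
or raw spectra, and biological correlations between assays. Passing
tests therefore demonstrate the *quantification* operations — not
robustness to every artifact of real microscopy or MS data.

## Problem sizes and determinism

Simulation-based checks use 20 populations of 200 cells for parameter
recovery (matching the assay's n = 200 counting convention),
30 planted frames for detection metrics, 16 chromosomes for composite
profiles, 3 replicates for peptide tables, and an 8-cell end-to-end
movie run — sizes at which every check completes in seconds while the
statistical criteria (exact binomial 95% CI coverage, >= 0.95
confusion diagonal) remain meaningful. All randomness flows through
`numpy.random.default_rng` seeded from a single integer; identical
parameters including the seed produce byte-identical serialized
outputs, asserted by writing the full pipeline twice and comparing
files byte for byte.

## Known limitations

* Detection is 2-D after projection; no 3-D segmentation, and no
  tracking beyond nearest-neighbor linking of at most two foci.
* The Yen threshold on sparse-spot images sits just above the
  background mode (see above); very close foci merge at that level.
* `classify_homozygous` needs pole information; the nearest-pole
  heuristic requires the caller to supply plausible pole positions.
* Composite profiles assume per-bp dense tracks in memory; for
  full-genome scale a windowed reader would be needed.
* FWHM/width fitting of line-profile peaks, peak calling, PSM-level
  FDR and phosphosite localization scoring are out of scope.
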