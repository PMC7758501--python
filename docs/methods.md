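# Methods

## The measurement model

A section image is a 2-D grid of non-negative integers in the inverted
densitometric convention: stronger chromogen deposit (darker in the raw
scan) maps to a larger gray value. RGB scans are reduced with ITU-R 601
luminance weights (0.299/0.587/0.114), rescaled to 16 bits and complemented
(`65535 − gray`). All downstream arithmetic happens on this scale.

**Background subtraction.** The background is the grayscale opening of the
intensity landscape by a hemispherical structuring element — the highest
surface a ball of the given radius, rolled beneath the landscape, can touch.
We use a true ball (height `sqrt(r² − d²)` in gray levels at lateral offset
`d`), not the paraboloid approximation some tools substitute, because the
ball has a clean oracle: brute-force min-then-max over the structuring
element must reproduce it exactly, and the test suite asserts that it does.
For radii above 16 px the opening is computed on a subsampled grid with a
correspondingly subsampled ball and interpolated back, clamped below the
image; this approximation is held to ≤ 1% mean absolute error of the image
range against the exact opening on 64×64 fixtures. Borders are handled by
edge replication. The default radius is 500 px, the standard protocol value
at whole-slide scanner resolution (~1 µm/px, i.e. a ~0.5 mm ball). For the
20 µm/px synthetic rasters the physically corresponding ball is a few tens
of pixels; simulated runs use a 2000 µm ball (~100 px), which like the
protocol ball is larger than any tissue structure of interest, so the matrix
plateau survives subtraction while illumination-scale trends do not. A
radius exceeding both image dimensions is a parameter error.

**Denoising.** Euclidean-disk median filter (radius 5 px by default; edge
replication; for even-sized neighborhoods the upper of the two central
order statistics, matching `scipy.ndimage.median_filter`). The same
physical-units argument applies: 5 px at scanner resolution removes ~5 µm
speckle, so the calibration harness uses a 1 px median on its 20 µm/px
rasters. A 5 px median at that raster would be a 100 µm filter — it erases
whole striosomes and wraps every patch in a partial-volume halo, which is a
property of the coarse raster, not of the protocol.

## Sector geometry

Per hemisphere, from four landmarks (caudoputamen outline,
anterior-commissure lateral tip, accumbens-shell upper tip, plus the
contralateral outline):

* line 1 — the inter-hemispheric tangent, implemented as the line through
  the medial extreme vertices of the two outlines (the classical
  construction names it geometrically; this reading is fixed and tested);
* line 2 — parallel to line 1 through the AC lateral tip; its lateral
  intersection with the outline margin is `q`;
* line 3 — accumbens tip → `q`;
* line 4 — perpendicular to line 1 from the accumbens tip, taken as the
  dorsally running chord of the outline;
* line 5 — parallel to line 3 through the midpoint of line 4 ("divide
  evenly" is read as bisection, consistent with the construction's own use
  of midpoints);
* line 6 — through the midpoints of the striatal chords of lines 3 and 5,
  extended to the outline boundary (the construction does not prescribe
  how far line 6 extends; we extend it fully).

Line 5 divides dorsal from ventral, line 6 medial from lateral; each sector
is the outline ∩ one quadrant. Masks are rasterized by pixel-center
membership (even-odd fill) of the outline, then classified by the two
signed half-plane tests — so the four sector masks partition the whole mask
*exactly by construction*, not merely up to rounding. A pixel exactly on a
divider counts as dorsal/medial, which realizes the stated DM-first tie
rule deterministically. Rasterization accuracy is checked against shoelace
areas of hand-constructed quadrilaterals (≤ 1%) and mirror symmetry of
random landmark sets (≤ 0.5% pixel disagreement; exact in practice).

## Segmentation

Each region (whole caudoputamen, and the four sectors at rostral levels) is
thresholded independently by the Li minimum cross-entropy method: the
Li–Tam mean-ratio fixed point (converged at |Δt| < 0.5 gray level) followed
by a global check of the criterion over all candidate split points, so the
returned threshold always attains the exhaustive minimum (on plateaus, such
as two-level histograms, the fixed point picks the canonical interior
value). 16-bit data are binned to 256 levels when they carry more distinct
values than that, and the threshold maps back to the original scale.
Supra-threshold pixels are striosome; ties go to matrix, making results
bit-reproducible. Constant regions are reported unsegmentable.

Two guards distinguish a genuine compartment split from the split Li must
produce even when no compartments exist:

* **separation guard** — if the class means differ by ≤ 6 pooled
  within-class standard deviations the region is reported as having no
  detectable striosomes. On measured sections the two cases are cleanly
  bimodal: genuine splits sit at ratio ≥ ~14 under the default conditions
  (60-gray-level gap, sd 5 noise), whereas splits of unimodal noise,
  residual shading or partial-volume rims sit at ≤ ~4. The ratio is
  invariant under global intensity rescaling, unlike an absolute floor.
* **minority-compartment guard** — striosomes are anatomically the minority
  compartment; a supra-threshold class covering > 60% of a region marks the
  split as non-compartmental (e.g. the dim partial-volume rim at the
  outline border becoming the "matrix").

**Fiber exclusion.** The exclusion threshold is the mean gray value of the
control squares (50 µm side, converted to pixels and rounded, at least
1 px) averaged across squares and truncated to an integer; pixels at or
below it move to the excluded class. Control intensities are measured on
the same processed image used for densitometry. Mask-level exclusion runs
after compartment segmentation, but the Li histogram already omits pixels
at or below the fiber threshold: a region with sparse striosomes plus one
dim pencil-fiber bundle otherwise makes the cross-entropy criterion prefer
the fiber/tissue gap and classify essentially the whole region as
striosome. With noise present the truncated-mean threshold sits at the
fiber intensity's center, so roughly half the fiber pixels fall above it;
exact exclusion recovery therefore holds in the noise-free limit and is
partial (but genotype-symmetric) under noise — an inherent property of the
control-square rule, not of this implementation.

## Metrics

Per region: `percent_area` = striosome pixels / (region pixels − excluded
pixels); compartment mean intensities; `ismp` = striosome ÷ matrix mean
intensity (predominance > 1); `total_intensity` = striosome intensity ×
%area (the integrated striosomal signal; an integrated-density column is
also emitted). Hemispheres are separate analysis units (16 caudoputamen
samples from 8 animals), the standard design for this assay; collapsing to animals
is a caller-side sensitivity option. A region with no detectable striosomes
reports %area 0 and total 0 — "no signal" is a measurement — with NaN
intensities/ISMP and `valid=False`.

## Statistics

Kruskal–Wallis (tie-corrected, chi-square reference) as omnibus, pairwise
two-sided Mann–Whitney U afterwards, reported regardless of the omnibus but
annotated when the omnibus is not significant. Exact Mann–Whitney p-values
(complete null distribution) are the default for untied samples of ≤ 8 per
group; tied or larger samples use the tie-corrected normal approximation
with continuity correction; exact mode refuses ties and falls back with a
notice. Degenerate inputs are pinned: constant pooled data give H = 0,
p = 1; a zero-variance normal approximation gives p = 1. Bonferroni
adjustment multiplies by an explicit family size, default 10 — so at
α = 0.05 the effective raw threshold is 0.005, matching the convention of
reporting significance at p < 0.005 after correction — and every output row
records the family size actually applied. Tests are two-sided throughout:
the direction of change is a finding, not a prior.

## The synthetic-section generator

The generator emulates what the analysis assumes about real sections, with
exact ground truth:

* **anatomy** — two caudoputamen outlines (48-vertex ellipses with smooth
  low-order radial jitter, ~1.5 × 1.2 mm at 20 µm/px), a corpus callosum
  band hugging the dorsal rim, anterior-commissure blobs near the ventral
  midline (carrying the two control squares), and small pencil-fiber
  bundles inside the caudoputamen. Jittered anatomies that make the sector
  construction degenerate are re-drawn, as a human annotator would never
  emit impossible landmarks. Landmarks are written in the same JSON schema
  the pipeline reads, so synthetic data exercise the real I/O path.
* **striosomes** — a Gaussian-smoothed white-noise field (correlation
  length 2.5 px ≈ 50 µm, giving ~100–250 µm patches), tilted by a linear
  dorsoventral gradient (dorsal rim enriched) and thresholded at the
  quantile that realizes the target area fraction (default 15% rostral,
  12% caudal — the literature range for striosome coverage; the value is a
  config knob, not a claim). Striosome and fiber masks are disjoint.
* **intensities** — integer expected values per compartment: matrix 120,
  striosome 180 (a 60-gray-level gap), fiber 60, slide background 10.
  Genotype × age × sector shifts follow the qualitative disease pattern:
  mutant striosome intensity +30 in DL at 3 and 6 months, +30 in DM/DL/VL
  at 12, +40 everywhere at 19; mutant matrix +15 in DL/VL at 12 and +30
  everywhere at 19; caudal wildtype striosome gain 0 (invisible) versus
  full-contrast caudal mutant striosomes at every age. Per-animal random
  intercepts (one integer offset per compartment, sd 3) emulate biological
  replicate variance.
* **noise** — multiplicative low-frequency shading (amplitude 3% of a
  smooth unit field) times the expected image, plus additive Gaussian noise
  (sd 5), rounded and clipped to 16 bits.

Because every expected value is an integer and ground-truth metrics are
computed from integer pixel sums over the very masks the renderer painted,
noise-free renders reproduce the stored true metrics *exactly* — the basis
of the exact-recovery tests.

What the generator does **not** emulate: real DAB chemistry and its
nonlinearities, antibody-specificity artifacts, tissue tears/folds,
section-to-section registration error, and scanner-scale resolution (its
rasters are ~20× coarser, which is why the physically scaled preprocessing
parameters above exist). Passing tests therefore demonstrate correctness of
the measurement chain under the stated statistical structure, not
robustness to every histological artifact.

## Calibration experiments

Two Monte-Carlo experiments run the full chain (generate → preprocess →
sectors → segment → exclude → quantify → cascade) per replicate cohort:

* **pattern detection** — cohorts with the programmed disease pattern at
  the earliest and latest ages (8 animals per genotype × age, both
  hemispheres, both levels; 64 images per cohort). A replicate "succeeds"
  when the flagged comparisons show: DL striosome intensity flagged at the
  earliest age with DL matrix *not* flagged; whole-region matrix flagged at
  the latest age; caudal %area and total intensity flagged at both ages.
  The acceptance test requires ≥ 90% success over 100 replicates.
* **type-I control** — null cohorts (identical compartment intensities for
  both genotypes, striosomes visible) of 3 animals per cell at one
  age/level; the familywise flag rate over 500 replicates must stay at or
  below α plus two Monte-Carlo standard errors. Bonferroni at family 10
  makes the cascade conservative, and the exact-test discreteness at these
  sample sizes more so.

Problem sizes (replicate counts, cohort sizes, raster scale) are chosen so
the full suite runs comfortably on a single CPU; they are stated here and
in the code rather than hidden in fixtures.

## Reproducibility and blinding

Every random quantity derives from one integer seed via spawned
`SeedSequence` children: cohorts are byte-for-byte reproducible, pipeline
runs with the same config + seed produce identical CSVs, and resumed runs
equal fresh runs. Measurement is structurally blinded: `analyze_section`
accepts no group metadata, and genotype/age join the measured rows only at
the statistics stage.

## Known limitations

* The control-square rule yields partial fiber exclusion under noise (see
  above); fiber that is brighter than the control tracts is not excluded.
* Per-sector striosome density fluctuates across realizations (the
  spatially correlated field is quantile-controlled per hemisphere, not per
  sector), so individual sectors occasionally have too few striosomes to
  segment; such regions are reported undetectable rather than guessed.
* %area is measured after thresholding a blurred raster and therefore
  carries a resolution-dependent negative bias relative to the painted
  truth under noise; group contrasts are unaffected (the bias is
  genotype-symmetric), and the noise-free limit is exact.
* The exact Mann–Whitney treats the two hemispheres of one animal as
  independent; with per-animal intercepts this is pseudo-replication,
  mirrored from the source design. Mixed-effects modeling is out of scope.
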