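# Methods

`mitoscan` re-implements, as a tested pipeline, the image-analysis and
statistics layer of a fixed-cell high-content RNAi screen for cell-division
phenotypes, together with the downstream combination statistics used on
loss-of-function (LOF) transcriptomic and chromatin-profiling data.  Because
the original raw microscopy cannot be reproduced at desk scale, a synthetic
image generator with complete per-cell ground truth stands in for the screen
data; every pipeline claim in the test suite is therefore a statement about
recovery of known simulated truth, not about real micrographs.

## The synthetic screen generator (`mitoscan.simulate`)

A well is a single 640×640 px field at 0.65 µm/px (the scale of a ×20 air
objective), with channel sets matching the two screen configurations:
`screenB` = DNA (Hoechst), α-tubulin, phospho-histone H3 (PHH3), γ-tubulin;
`screenA` = DNA, α-tubulin, CEP215, actin.  Cells are soft-edged elliptical
blobs convolved with a Gaussian PSF (σ = 0.4 px), over a background of 8
intensity units, with Poisson noise (gain 0.25) and Gaussian read noise
(σ = 1.5).  Intensity units are arbitrary by design: the screen's exposure
scale is not part of the model, and all classifier thresholds are expressed
on the generator's documented scale.

Phenotype classes and their rendered signatures:

| class          | DNA                                   | other channels |
|----------------|---------------------------------------|----------------|
| interphase     | large ellipse (semi-axes ~7×6 µm, amp ~60) | cytoplasm tubulin disc (amp ~25) |
| mitotic        | condensed: small bright disc (r ~3.5 µm, amp ~120) | PHH3 over chromatin (amp ~60), bright spindle tubulin |
| ana/telophase  | two small plates (amp ~110) elongated perpendicular to the division axis, boundary gap 1.8–2.45 µm | PHH3-positive; telophase adds a bright tubulin midbody + γ-tubulin spot |
| multinucleated | 2 (binucleate) or 3 (step-2 type) round nuclei in one cell body | trinucleates have low cytoplasmic tubulin (failed cytokinesis) |
| dead/debris    | small bright fragment (r 3–3.5 µm)    | no tubulin staining |
| bridged pair   | two interphase cells 24 µm apart      | two bright tubulin half-bridges flanking a dim midbody gap, γ-tubulin midbody spot |

Chromosome-segregation errors (CSEs: chromatin bridges / lagging chromatids)
are rendered as a thin DNA filament (amp 22, ~2 px wide) spanning the
inter-nucleus gap of an anaphase (or telophase) figure.  The filament
amplitude is deliberately below the nuclear segmentation threshold, as a real
chromatin bridge is far dimmer than a chromosome mass.

Geometry and amplitude defaults are free parameters of the generator — the
source workflows publish no rendering model — chosen once so that the default
rule cascade separates the classes; they are fixed in `simulate.GEOM` and not
tuned per experiment.  The generator does not model cell motion, 3-D
structure, illumination gradients, or photorealistic texture; consequently
the recovery results bound what the rule cascade can do on well-behaved
images, not its performance on real screens.

Randomness: one master seed per well; a plate derives per-well seeds via
`SeedSequence(plate_seed, spawn_key=(row, col))`, so any well is reproducible
in isolation and rendering is bit-for-bit deterministic given its config.

The plate batch effect is a multiplicative factor applied to the per-well
*ratios* (true and measured alike), modelling a plate-wide staining/detection
gain.  Applying it post-measurement keeps the defining identity exact (a
factor-2 plate has exactly twice the ratios of its factor-1 twin under the
same seed) and is what mean-scaling normalization removes exactly.

## Segmentation (`mitoscan.segmentation`)

Nuclei: global Otsu threshold on a lightly smoothed (σ = 0.6 px) DNA channel,
distance-transform watershed with peak seeds at least 5 px apart, minimum
object area 20 µm².  Peak suppression in `peak_local_max` is global, so a
small object close to a brighter neighbour can lose all its seeds; such
components are re-seeded at their distance-transform maximum.  Cytoplasm: a
nucleus-seeded watershed over the tubulin foreground (triangle threshold —
robust when bright spindles/bridges skew the histogram), giving one cytoplasm
label per nucleus.  Features per object: area, ellipse axes, aspect ratio,
roundness 4πA/P², per-channel integrated/mean intensity, and the mean in a
2 µm perinuclear ring excluding all other objects.  All sizes are physical
(µm) via the image pixel size.

## The rule cascade (`mitoscan.phenotyping`)

Order of operations: dead filter → mitotic gate → anaphase/telophase pairing
→ CSE scoring → multinucleation → cytokinetic bridges → counting.

* **Dead filter** — area outside [14, 500] µm² or mean tubulin below 15
  (debris carries no cytoskeleton).
* **Mitotic gate** — condensed DNA (area ≤ 70 µm², mean DNA ≥ 80) plus high
  PHH3 (≥ 30) in screenB, or high tubulin / low CEP215 in screenA.
* **Pairing** — candidates are mitotic nuclei that are small (≤ 40 µm²),
  elongated (aspect ≥ 1.5) and below the 0.95 quantile of mitotic integrated
  DNA (each anaphase mass carries half a complement); greedy mutual-nearest
  pairing on the boundary gap; pairs beyond the telophase distance limit
  (2.6 µm) are discarded as separate daughter cells.
* **Stage** — decided by α-tubulin in a narrow corridor (0.4× the mean minor
  axis wide) between the nuclei: anaphase has the *lower* inter-nucleus
  tubulin, telophase the bright midbody.  The printed anaphase/telophase
  distance maxima (0.65 / 2.6 µm) cannot discriminate the stages at
  0.65 µm/px (they are sub-pixel quantities), so the default `stage_by`
  is `"tubulin"`; `"distance"` and `"both"` modes apply the per-stage
  distance gates instead, and `anaphase_tubulin_lower=False` inverts the
  tubulin direction — never silently.
* **CSE** — mean DNA in the inter-nucleus corridor (0.5× mean minor axis
  wide) against background mean + 3 background SDs.  The corridor excludes a
  disc of radius half the fitted minor axis (+1 px) around each nucleus
  rather than the raw masks: a chromatin bridge bright enough to be
  thresholded joins the two nucleus masks, and mask-based exclusion would
  erase the very signal being measured.  The exclusion radius is capped at
  0.42× the centroid distance so a central strip stays measurable; a corridor
  fully swallowed by the exclusions scores negative with a warning.
* **Multinucleation** — step 1 pairs close (≤ 12 µm), round
  (roundness ≥ 0.75, aspect ≤ 1.6), normally-sized nuclei whose perinuclear
  tubulin is *not* low; step 2 groups remaining low-perinuclear-tubulin
  nuclei sharing a connected tubulin cell body.  Restricting step 1 to
  intact-cytoskeleton nuclei keeps trinucleates from being split into a pair
  plus a singleton.
* **Bridges** — bright tubulin (> 65) components that are elongated
  (eccentricity ≥ 0.88, length 2–6 µm), paired into doublets with a gap of
  0.5–5 µm, joining two *distinct* cytoplasm labels, with a γ-tubulin spot
  within 2.5 µm of the doublet midpoint (configurable off).  The distinct
  label requirement rejects stress-fibre-like objects inside one cell.
* **Counting** — each pair and each multinucleate group is one viable cell;
  dead objects are excluded from denominators; mitotic index counts mitotic
  figures plus ana/telophase pairs over viable cells; the CSE rate is per
  anaphase; wells with empty denominators report 0 plus a quality flag so
  tables stay rectangular.

Every "high"/"low" threshold is a config field on the generator's intensity
scale and also accepts `"auto"` (Otsu over the per-object distribution).
Fixed numeric defaults were preferred over per-well auto thresholds because
Otsu is unstable when a class is absent from a well — the common case for
rare phenotypes — whereas a screen fixes thresholds once on control wells.

## Screen statistics (`mitoscan.screen_stats`)

Ratios are normalized between plates by mean scaling: the grand average of
per-plate means is the reference ratio; per-well ratios are scaled so each
plate's mean equals it (a zero-mean plate keeps factor 1 with a warning).
Z-scores follow z = (x − μ)/σ with x the normalized ratio, μ the reference
and σ the sample SD of normalized ratios across wells.  μ and σ are estimated
over library (non-control) wells by default — hit calling compares each
target to the library mean — with `include_controls` to override.  Hits are
targets whose mean z across their wells passes the threshold in the requested
direction, ties broken lexicographically.  Replicate concordance is
Spearman's rank correlation with average-rank ties, over wells or targets
matched by id.  No spatial or multivariate correction (B-scores, edge
effects) is applied; only mean scaling is modelled.

## The mini-screen (study conditions)

`pipeline.run_mini_screen` simulates a validation-type screen: 46 library
targets, two wells per target per plate plus four negative-control wells
(96-well plates), four plates per replicate carrying batch factors
{0.7, 1, 1.3, 2}, two replicates — eight technical wells per target and
replicate, 768 wells total, ~100 cells per well.  Per-target baseline mitotic
fractions are drawn once from LogNormal(ln 0.045, 0.45) clipped to
[0.012, 0.25], modelling the genuine spread of depletion phenotypes across an
siRNA library; ~5% of wells belong to designated hit targets whose mitotic
fraction is set to 0.15, three times the 0.05 baseline class fraction.  Each
target is scored by the z of its mean normalized ratio against the library's
distribution of per-target means — in a one-well-per-target screen this is
identical to the per-well z, and with technical replicates it is the natural
reading of scoring each target "based on the mean mitotic index".  Hit recall
and the false-positive rate are evaluated at z ≥ 2; replicate concordance is
the Spearman correlation of per-target normalized mitotic-index means between
replicates.  With ~100 cells per well
the per-well mitotic-index standard error is ≈ 0.02 — nearly half the
library's between-target spread — so the eight-fold technical replication is
what makes both hit recovery and replicate concordance achievable at once;
single-well-per-replicate layouts cannot satisfy both at this cell count.

## Quantification (`mitoscan.quantification`)

Spindle intensity: per z-plane, integrated intensity in a circular ROI
divided by ROI area, background subtracted, averaged over planes; the
acetyl-tubulin/α-tubulin ratio divides two such values, and EB1 levels use
the single-channel path.  Background defaults to the mean of an annulus at
1–1.5 ROI radii (per stack, not per plane) when not supplied.  Inter-
kinetochore distances are Euclidean distances of manually picked sister-
kinetochore pairs in one focal plane, scaled by pixel size, with per-cell
mean/median summaries.  ROIs and kinetochore pairs are user input; no
automatic spindle or kinetochore detection is attempted.

## Combination statistics (`mitoscan.enrichment_stats`)

The module consumes p-value and window tables; the upstream count models
(voom/edgeR/csaw fits) are out of scope.

* **IUT** — per gene and direction, the combined one-sided p is the maximum
  across LOF methods.  How the two directional values become one per-gene
  significance is not uniquely determined; the default assembles them
  two-sidedly (2 × the smaller directional p, capped at 1) and
  `assembly="per-direction"` keeps each direction for separate FDR control.
  Both readings are exposed rather than silently picking one.
* **Windows** — BED-convention 0-based half-open intervals from a 150–1000 bp
  size sweep; abundance filtering keeps windows ≥ 5× expected background
  coverage; single-linkage clustering merges transitively overlapping
  windows per chromosome (order-independent); Simes' method
  (min over sorted p of m·p₍ᵢ₎/i) gives each cluster a combined p;
  Benjamini–Hochberg defines discoveries at FDR 5%.
* **eFDR** — among clusters passing a combined-p cutoff, the ratio of
  sense-control-enriched ("down") to antisense-pulldown-enriched ("up")
  clusters; a sweep finds the largest cutoff with eFDR ≤ 30%.  An empty
  denominator reports eFDR 1 with an `undefined` flag (maximally
  conservative).  Mixed-direction clusters take the direction of their
  smallest-p member.

## Numerical and degenerate-input conventions

Coordinates are 0-based (row, col); distances and areas are physical via
pixel size.  Boundary gaps are measured as minimum pixel-centre distance
minus one pixel, floored at zero.  Deterministic tie-breaks throughout:
pairing and doublet matching process candidates in increasing distance then
label order; hit ties break by target id.  Constant images segment to zero
objects; empty wells produce zero counts with flags; σ = 0 in Z-scoring and
empty p-value lists raise rather than return NaN.

## Problem sizes

The test suite and the acceptance script run the mini-screen at its full 768
wells, the parameter-recovery sweep at 96 wells (mitotic fractions 0.02–0.30,
CSE rates 0–0.5, bridge rates 0–0.08), the CSE benchmark at 16 anaphase-rich
wells (~275 matched anaphase events), the statistic oracles at 1000
randomized inputs of size ≤ 8, and the null-calibration of IUT+BH at 10,000
genes.  These sizes were chosen so a complete run finishes in minutes on one
CPU while keeping every estimate's Monte-Carlo error well inside the margins
being tested.

## Known limitations

Pairing recall for anaphase figures is ~90% (merged masses at small gaps are
lost to the watershed); CSE sensitivity is conditional on the pair being
found.  Trinucleate recovery degrades when a neighbouring cell's tubulin
contaminates the perinuclear ring.  The classifier's fixed thresholds assume
the generator's intensity scale; real images would need the `"auto"` mode or
recalibration.  The batch-effect model is purely multiplicative at the ratio
level; spatial plate effects are not modelled.
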