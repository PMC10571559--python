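# Methods

## The assay and what the pipeline measures

A clonogenic survival assay seeds `S` single cells into a well; each cell
independently survives treatment and founds a colony (clone) with
probability `p`. The classical readout counts clones of at least 50 cells:
plating efficiency PE = clones/S, surviving fraction
SF = PE_treated / PE_control. Imaging the wells replaces the binary count
with per-nucleus and per-clone measurements, and RGB barcoding (six
additive classes R, G, B, RG, RB, GB) lets clones that touch in dense
multiwell plates be separated by color.

## Synthetic plate model

The generator (`clonoscope.simulate`) is the ground-truth oracle for the
whole pipeline. Its model, per well:

- **Survival**: each of `seeded_cells_per_well` (default 200, the highest
  seeding density that keeps clone counts stable over days) survives with
  probability `survival_prob`; surviving clones get uniform positions with
  a margin, a color class drawn from `color_mix` (uniform over six by
  default), and a log-normal cell count (median 8 cells, log-sd 0.35 —
  compact early-timepoint clones).
- **Clone geometry**: member nuclei are placed by a sequential growth
  model. The founder takes the clone center; every further cell attaches
  one step away from a randomly chosen existing member at a random angle,
  and among the valid candidate sites the one nearest the clone center is
  kept, so colonies fill inward gaps before sprawling outward. The step is
  `max(1.5·dmin, clone_dispersion_px)` with `dmin = 0.85 × minor axis` the
  minimum center spacing. The spacing applies across clones as well:
  monolayer cells exclude each other regardless of clone membership, and
  without it, overlapping different-color clones could stack nuclei
  exactly on top of each other, producing hybrid two-color objects that
  no real plate would show. This growth model mirrors how colonies
  actually form — daughters sit adjacent to their mothers — and produces
  compact, **connected** clones whose internal neighbour gaps are bounded
  by about two steps. A Gaussian cloud and a uniform disk were both
  rejected: their unattached sampling leaves isolated members and
  interior gaps that no density-based clustering could attribute to the
  right clone, an artifact of the sampler rather than a property of
  colony growth. `min_nucleus_spacing_px` overrides the spacing to build
  fixtures of fully resolvable cells.
- **Nuclei**: ellipses with axes 12 × 9 px (typical ~10 µm nuclei at 10×
  with ~0.7 µm pixels), random orientation, rendered as anisotropic
  Gaussian profiles with σ = semi-axis/2 (the nominal ellipse is the
  2σ contour). Total intensity is proportional to area with log-normal
  cell-to-cell variation (log-sd 0.15); the peak amplitude is therefore
  approximately constant across nucleus sizes, as for a stain of constant
  areal density. In the single-channel DNA arm, a `g2_fraction` of nuclei
  carries twice the intensity (G2/M DNA content). In the barcoded arm the
  full intensity is added to every channel of the color class (an RG
  nucleus is equally bright in R and G).
- **Fragments / micronuclei**: a `fragment_rate` fraction of nuclei is
  replaced by 2–4 pieces with areas uniform in [0.15, 0.42] × the median
  nucleus area, intensity reduced proportionally, placed around the parent
  with a minimum spacing and clear of intact nuclei. The lower bound marks
  the sub-resolution limit at this pixel scale; the upper bound keeps
  every piece under half a nucleus.
- **Camera**: tiles are cut from one noise-free scene, so overlap strips
  agree exactly before camera effects; each tile is then multiplied by a
  radial gain field (1 at the center, 1 − amplitude at the corners,
  default amplitude 0.15 over a background offset of 500 counts), receives
  Poisson noise (gain 0.25 counts/photon) plus Gaussian read noise
  (σ = 3 counts), and is quantized to uint16. Noise and illumination
  amplitudes are instrument properties, not assay properties; the defaults
  are plausible wide-field values and are exposed in the config.

What the generator does **not** emulate: optics (no PSF, no defocus), well
edges and debris other than nuclear fragments, autofluorescence texture,
spectral crosstalk in rendered images (crosstalk is modeled in the
feature-level classifier fixtures only), uneven cell spreading, and clone
merging over time (per-day tables are generated independently). Passing
tests therefore demonstrate correctness of the algorithms under a clean
but non-trivial forward model — touching nuclei, cross-border clones,
gradients, shot noise — not robustness to every artifact of real plates.

## Pipeline stages and numerical choices

**Stitching.** Coordinates are 0-based pixels, x right / y down, origin at
tile (0,0). The rough mosaic places tiles at nominal origins (per-pixel
maximum in overlaps) and downsamples by 4. Clone tiles are those whose
rectangle intersects a connected component of the Otsu foreground of the
mosaic. For each adjacent pair of clone tiles the relative integer shift
maximizing normalized cross-correlation (template drawn from the overlap
strip with a ±20 px search margin) is estimated; shifts propagate through
a spanning tree anchored at the smallest grid position of each connected
component. Strips without signal variance are skipped with a warning.
The search range requires `overlap − 2·max_shift ≥ 3` px. In the final
composite each pixel is owned by the tile whose center is nearest — no
blending, because blending distorts the total-intensity measurements used
for DNA content — which also guarantees a cross-border object appears
exactly once.

**Background.** The gradient is estimated per tile before stitching
(the optics make it a per-tile field). Objects are masked by Otsu, with a
contrast guard: if the bright class is less than 1.5× the dark class the
tile is treated as object-free (otherwise Otsu merely bisects the
background gradient itself); the object mask is then dilated by about
half a patch width, because nucleus tails extend well past the Otsu
boundary and would silently lift "object-free" samples. Twenty sample
points are chosen one per cell of a spread grid whose ideal positions
span the full tile including the borders (minimizing extrapolation); the
local value is the median of the object-free pixels in a 15×15 window. A
quadratic surface is fitted by least squares with iterative sigma
clipping — a sample landing in the faint skirt of a clone can sit
hundreds of counts above the true background, and one such outlier among
twenty would otherwise warp the whole surface. A thin-plate-spline
correction of the residuals is added only when the residual RMS exceeds
twice the level predicted by the pixel noise (estimated robustly from
first differences of object-free pixels) — otherwise the spline would
interpolate sampling noise. The residual term
extends flat beyond the sampled region; the polynomial extends smoothly.
With fewer than 4 object-free samples the surface falls back to the global
median with a warning. Subtraction clips at zero. With 20 noisy samples
the per-tile maximum surface error has irreducible fit variance of ~1–2%
of the gradient amplitude; averaged over tiles it is comfortably below 2%.

**Segmentation.** Detection runs on the channel sum. The threshold is the
knee — the point of maximum curvature, located as the sample farthest from
the endpoint chord — of the range-normalized descending sorted-intensity
curve of the lightly smoothed image (σ = 1 px), with Otsu fallback and a
noise floor of five pixel-noise sigmas — in very sparse wells the knee
can land inside the background noise, where random pixel clusters
masquerade as nuclei. The mask itself cuts the **raw** image at that
threshold: masking the smoothed image would inflate micronucleus areas by
~50% while full nuclei grow only ~10%, corrupting normalized-area
statistics. Components below 9 px² are dropped (tallied, not silent), and
border-touching components whose eroded core is dimmer than their shell
(bright-rim well-edge artifacts) are removed. Touching nuclei are split
by marker-controlled watershed; markers are local maxima (minimum
separation `h_min`, default 3 px ≈ a third of a minor axis — half a minor
axis already merges the dimmer peak of a touching pair) of the smoothed
intensity when an image is available — fused Gaussian-profile nuclei keep
distinct brightness peaks long after their outlines merge, where
distance-transform maxima do not — or of the distance transform for
binary-only input. In multichannel wells, per-channel intensity peaks
augment the marker set: two touching nuclei of different barcode colors
can fuse into a single peak in the channel sum while staying clearly
bimodal per channel, and leaving them merged creates hybrid two-color
objects that corrupt clone calling.

**Shape descriptors.** Roundness = 4A/(π·major²) with the moment-based
major axis; circularity = 4πA/P² with perimeter *and* area taken from the
same subpixel contour polygon (marching squares on the smoothed mask at
level 0.5). Pixel-counting perimeter estimators are biased by 10–30% at
micronucleus scale and can push circularity to 1.2–1.3; the polygon
estimator stays within [0.94, 1.0] for rendered ellipses of every size and
respects the isoperimetric bound. Both descriptors are capped at 1.05
(discretization slack).

**Color classification.** Features per nucleus: per-channel mean
intensity, channel fractions, log total intensity, area, circularity.
Fractions use the 3×3-pixel window at the region's brightest pixel
("core" intensities) when available — the core is far less contaminated
by the Gaussian tails of touching neighbours of other colors than the
full-region sum. The decision tree (Gini, unlimited depth, fixed seed 0)
is serialized to explicit JSON rules so saved models reload with identical
predictions. The rule-based fallback marks a channel "on" above a 0.25
fraction and maps the on-set to the six classes; empty or full on-sets are
TRASH.

**Clone calling.** DBSCAN (scikit-learn) on centroids, Euclidean, default
`min_samples` 3; run per color class when barcoded, one global run
otherwise, since the assay's own grouping rule for the classical arm is
the same spatial-density notion. Noise points become singleton clones —
small clones below any counting threshold remain countable. Automatic
`eps` is the knee (maximum chord distance) of the sorted k-distance
curve, which marks the upper edge of the within-clone neighbour-distance
distribution — about one nucleus length in confluent colonies. A floor of
2× the median nucleus major axis guards against degenerate collapse
(duplicated or stacked points drive the knee to zero) and replaces the
knee only when the knee falls below half the floor: a healthy knee
legitimately sits below two nucleus lengths and must not be overridden.
The floor uses the intensity-weighted axis when available, because the
binary-moment axis of a soft-edged nucleus grows as the detection
threshold drops. Clone area
is the convex hull of member centroids (≥ 3 non-collinear members; summed
nucleus area otherwise); compactness is cells per normalized clone area.
Longitudinal analysis reports per-day counts and cells-per-clone
distributions only — no cross-day identity tracking.

**Survival statistics.** Cutoffs follow assay convention and live in
`ThresholdConfig`: ≥ 50 cells per counted clone; small nuclei below 0.5 of
the well-median normalized intensity or area; large nuclei within [3, 10]
normalized intensity or [2, 4] normalized area (the bracketed band rather
than an open tail, which would also catch stitching artifacts); roundness
< 0.5; circularity < 0.9. All six fractions share one denominator (all
non-TRASH records). DNA-content histograms use 80 bins on [0, 4],
normalized to unit mass; mode positions are refined by parabolic
interpolation after a 1-bin Gaussian smoothing, which removes bin
quantization from G2/G1 position ratios. Optimal seeding density is the
highest density whose clone count deviates from its across-day mean by at
most 15% on every day.

**Screen analytics.** Raw per-well metrics (plating efficiency, median
nuclei per clone, IQR of nuclei per clone as clone-size heterogeneity,
median nucleus size, median circularity) are averaged over replicates and
divided by the same-cell-line untreated control, so control rows are
exactly 1. Treatments are clustered on columns standardized to zero mean
and unit variance (constant columns dropped with a warning) by Ward
linkage on Euclidean distance, cut at k = 3; Ward was chosen for compact
balanced classes and is exposed in config. Heterogeneity is normalized by
the control IQR (one of several defensible readings of "normalized
heterogeneity"; stated here explicitly). Correlations (Pearson and
Spearman) of each metric against survival fraction report NaN, not zero,
for constant metrics. The mock screen assigns 20 drugs cyclically to
three effect tiers — none, moderate, strong kill — that scale survival
probability, clone growth and nucleus size per dose with known values,
and runs each well's ground-truth nuclei through the real clone-calling
and metric code (rendering 246 well images would add ~50× runtime without
exercising any additional screen logic; the imaging stages are validated
by the stitching/segmentation checks).

## Problem sizes

Default study conditions: one well = a 3×3 grid of 768×768 px tiles at
10% overlap (stitched ≈ 2150² px), 200 seeded cells, ~1600 nuclei. The
validation script simulates 10 such wells for clone-count recovery and 20
treated/control pairs for survival-fraction recovery; the test suite runs
the same checks on 3 wells and 4 pairs respectively, plus noise-free 2×2
fixtures for stitching and anomaly statistics. The mock screen is 2 cell
lines × (20 drugs × 2 doses + control) × 3 replicates = 246 wells at the
clone-table level.

## Known limitations

- Touching nuclei split by watershed have chord-like boundaries; their
  measured area and circularity are biased low relative to isolated
  nuclei, so anomaly-fraction agreement with ground truth is only
  guaranteed for wells whose cells are resolvable.
- Detection inside dense clone cores recovers ~92–95% of nuclei; clone
  counting is robust to this (a clone's identity does not depend on
  finding every member), but absolute cells-per-clone is a slight
  undercount in dense clones.
- Offset refinement is translation-only and integer-valued; rotation,
  scale and subpixel alignment are out of scope (counting and intensity
  statistics do not need them).
- The automatic `eps` assumes clone spacing well above nucleus size; in
  near-confluent wells it will merge clones, which is the regime the
  color constraint exists for.
- Saved color models are tied to this package's feature specification;
  a mismatch raises rather than silently reordering features.
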