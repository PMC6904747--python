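# Methods notes

This note records the scientific and numerical choices behind
`colonyflow`, the assumptions they rest on, and what the synthetic test
suite does and does not demonstrate about real microscope data.

## Problem setting

Human epidermal keratinocytes grown on a lethally irradiated 3T3
fibroblast feeder layer form densely packed, progressively growing
colonies.  In phase contrast, three contrast cues distinguish a colony
from the feeder background: nucleoli appear as dark spots, the nucleus as
a dark ring around them, and cell–cell boundaries inside the colony as a
bright mesh.  Feeder fibroblasts are sparse, elongated, and form no mesh.
The pipeline turns those cues into (i) a per-frame colony mask and (ii) a
collective locomotion speed inside that mask, the quantity that tracks
stemness and responds to metabolic or cytoskeletal inhibitors within one
or two 5-minute frame intervals.

## Colony extraction

**Adaptive binarization.**  Each pixel is compared with a weighted mean of
its 41 × 41 neighborhood; `polarity="dark"` keeps pixels below
`mean − offset`, `"bright"` those above `mean + offset`.  The weighting is
Gaussian with σ = window/6 (support clipped to the window); a plain box
mean is available via `binarize_method="box"`.  The weighting profile is a
choice, not a given — published descriptions of this step say only
"weighted average" — so it is exposed in the config.  The offset defaults
to 3 % of the intensity range: some nonzero margin is required or flat
background fluctuates into foreground.  Adaptive thresholding is
equivariant under affine intensity rescaling when the offset is scaled
with the image, which the tests assert.

**Nucleolus acceptance.**  Dark components with area in [12, 72] px
(inclusive on both ends; the size range is read as an AND-range, since an
OR of "≥ 12 or ≤ 72" would exclude nothing) become candidates.  A
candidate is accepted when (a) its rounded centroid pixel belongs to the
candidate itself — rejecting crescents and other concave debris — and
(b) the candidate lies inside a hole of other dark foreground, i.e. every
4-connected background path from it to the image border crosses another
dark region.  The enclosure test is computed globally: background
components touching the border are "outside", and a candidate adjacent to
outside background (or to the border) is rejected.  This is O(image) for
all candidates together rather than per-candidate flood fills.  Centroid
rounding is half-toward-smaller-index for determinism.

**Boundary mesh and branch points.**  The bright mask is opened then
closed with a 3 × 3 square (that order follows the procedure's
description; the element size is this package's choice), then components
of ≤ 250 px are removed with 8-connectivity (the labeling connectivity is
unstated in the source procedure; 8 matches the nucleolus stage).
Thinning is a faithful vectorized implementation of the classic
two-subiteration Zhang–Suen algorithm run to a fixed point, followed by a
single topology-preserving pruning pass that deletes one simple pixel from
each residual 2 × 2 block — such blocks are a known artifact of the
algorithm and would otherwise create spurious Crossing-Number junctions.
The tests pin the implementation to an independent per-pixel reference of
the same two-subiteration rules and cross-check against
`skimage.morphology.skeletonize(method="zhang")`, which keeps marginally
more end pixels (different update scheduling); pixel agreement is > 98 %
and all topological properties coincide.  Endpoint erosion of one to two
pixels per line end is inherent to the algorithm and harmless here —
junctions, not endpoints, carry the signal.

**Crossing Number.**  CN = ½ Σ|Pᵢ − Pᵢ₊₁| cyclically over the 8
neighbors, traversed clockwise from the top-left (the value is invariant
to start and direction; fixing one makes tests deterministic).  Border
pixels are evaluated with zero padding.  CN = 3 marks a branch point;
CN = 4 crossings are excluded by default (`include_crossings` adds them),
matching the stated rule that bifurcations carry CN 3.

**Kernel density estimate.**  Pooled landmarks (duplicates across classes
retained — each contributes kernel mass) feed a 2-D isotropic Gaussian KDE
with bandwidth h = 151 px.  The printed 1-D formula is generalized with
the proper 2-D normalizer 1/(2πh²); since the colony threshold is relative
to the frame's density maximum, the normalizer never affects the mask.
Evaluation is separable convolution of a landmark impulse image with a
1-D Gaussian along each axis, truncated at 6 h (error < 2 × 10⁻⁷ of the
density peak) and capped at the image diagonal; an FFT path with identical
semantics takes over when `pixels × radius` exceeds ~4 × 10⁸ operations.
Borders reflect kernel mass by default so colonies touching the frame edge
are not dimmed; `boundary="none"` reproduces plain truncated direct
summation, and the test suite verifies both engines against an
untruncated direct-sum reference to < 10⁻⁶ of the peak.  Pointwise
*relative* agreement is not a meaningful target in the far Gaussian tail,
where densities of order 10⁻⁶⁰ × peak sit far below float64 cancellation
in any convolution; peak-normalized error is the well-defined metric.

**Mask.**  The density is thresholded at `kde_threshold_frac` × max
(default 0.2; an absolute threshold mode exists) and the largest
8-connected region is kept, ties breaking toward the earliest raster
pixel.  Whether the original analysis used a relative or absolute
threshold is unknowable from its description; relative is this package's
default because it is invariant to landmark count and normalization.  No
correction is attempted when feeder aggregates touch a colony — the
method inherits that failure mode.  For flow, the mask of frame t is used
for the pair (t, t+1): the earlier frame keeps the region causal.

## Motion analysis

Dense flow backends are pluggable behind one contract (median recovered
vector within 0.5 px per component for rigid integer translations of
textured scenes).  The default is scikit-image's pyramidal iterative
Lucas–Kanade (`ilk`), with TV-L1 available; an exhaustive integer
block-matching oracle (16-px blocks, SSD, configurable search radius,
deterministic smallest-displacement tie-break) serves as the independent
test oracle and is exact on integer translations.  Flow is reported so
that content at (r, c) in frame t appears at (r + v, c + u) in frame t+1.
Sub-pixel magnitudes are averaged as floats — rounding would bias the
small-motion regime where metabolic inhibition lives.  Untextured frames
yield a zero field flagged low-confidence rather than noise.

Speed is the mean flow magnitude over the colony mask, converted to
µm/min only when the user supplies a pixel size (objective-dependent and
not recoverable from the images themselves); otherwise px/frame is
reported natively.  Variational backends have a noise floor of a few
tenths of a pixel per frame on weakly textured regions; it inflates
absolute speeds slightly (consistent with reports that dense-flow speeds
sit below manual-tracking speeds) but preserves ordering across
conditions, which is what the screen uses.  No correction is applied.

## Statistics

The sampling unit is the per-colony mean speed; pixelwise speed samples
are exported for violin plots only.  Two groups: unpaired two-tailed
Mann-Whitney U, exact null distribution when both groups have ≤ 10 values
and no ties (with 5 vs 5 and complete separation the exact two-tailed p is
2/C(10,5) = 0.0079), midrank normal approximation otherwise, with a
recorded note.  Three or more groups: tie-corrected Kruskal–Wallis H plus
Dunn's z-tests against a designated control on pooled midranks, Holm
adjusted — the adjustment is named in every output record because the
original analysis does not state one, and an adjusted p is never reported
below its raw p.  All-tied data is reported as H = 0, p = 1 by convention.

## Synthetic scenes

The generator produces contrast structure, not photorealism: jittered-grid
cell seeds inside a colony polygon; the bright mesh is the nearest-seed
partition boundary dilated to 3 px (so it survives the 3 × 3 opening);
each cell carries a 2-px dark ring at radius 8 and a dark nucleolus disc
of radius 3 (~25 px, inside the [12, 72] filter by construction); feeders
are dark 3 × 12 ellipses outside the polygon; decoy nucleolus-sized spots
without rings test the enclosure rule.  Motion (rigid translation or
radial expansion) is applied to the pre-noise scene by recursive bilinear
warping, so the truth field maps frame t exactly onto frame t+1 before
i.i.d. Gaussian noise (σ = 0.01 by default) is added per frame.

Three canonical suites define the evaluation conditions.  *Flow*: 256²
scenes with translations (0,0), (0,3), (−2,1) and amplitudes 0.5/1/2
px/frame plus one radial scene.  *Screening*: 512² scenes, five colonies
at 2 px/frame ("control") versus five at 0.1 px/frame ("inhibited"),
three frames each — the five-per-arm, complete-separation layout of a
two-condition inhibitor experiment.  *Segmentation*: ten single-frame
2304² fields with an eight-vertex colony polygon of mean radius 380 px and
varying cell density and feeder count.  The segmentation geometry follows
from the method's own scales: with h = 151 and a relative threshold of
0.2, the density contour of a smoothed indicator falls ≈ 0.85 h ≈ 127 px
outside the true colony edge, so the over-detected ring is ~2πR × 127 px
regardless of field size.  Meaningful pixel accuracy therefore requires
full microscope fields with colonies a few bandwidths across; on the suite
the pipeline scores ≥ 0.90 accuracy per scene with all-default
parameters, with over-detection as the dominant error term — the same
skew the method shows on real data.

What passing these suites does *not* show: robustness to uneven
illumination, focus drift, halo artifacts, mitotic rounding, colony
merging/fragmentation, or feeder aggregates touching colonies.  The
scenes exercise the pipeline's logic under its stated contrast
assumptions, not the variability of real cultures.

## Degenerate inputs and determinism

Empty landmark sets produce an all-zero density, an empty mask with a
reason flag, and skipped speed pairs with warnings — never silent zeros or
NaNs.  A single usable frame pair reports SD as absent, not 0.  Component
labels, centroid rounding, region tie-breaks, block-matching ties and all
RNG use (one seed per scene spec) are deterministic, and re-running a
pipeline on the same inputs reproduces outputs bit-identically.

## Problem sizes in the test suite

Unit tests run on 64–256 px images with bandwidths scaled accordingly
(h = 30 at 256 px keeps the mask/colony ratio comparable to h = 151 at
full field).  The acceptance-style suite runs the ten full-field
segmentation scenes and the ten-colony screening suite end to end with
default parameters; the whole test run completes in a few minutes on one
CPU.
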