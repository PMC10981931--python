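# Methods

## The trait and the measurement model

The quantity of interest is periderm (phellem) length: the arc length of
root, measured from the hypocotyl downwards along the root axis, that is
covered by suberized periderm. The package measures it on whole-slide
fluorescence scans of Fluorol-Yellow-stained roots. Two assumptions carry
the whole pipeline:

* **Contiguity.** Periderm develops as a single contiguous zone starting at
  the hypocotyl end of the root. Any predicted periderm separated from the
  hypocotyl-anchored zone by a large stretch of non-periderm is therefore
  treated as a segmentation error, not as a second periderm zone.
* **Texture separability.** In FY images the two suberized tissues differ
  in cell geometry — periderm consists of small, irregularly shaped bright
  cells, endodermis of long rectangular cells — so per-pixel texture
  statistics suffice to tell them apart; no shape prior on whole roots is
  needed.

The measured "whole-root length" is the visible mounted fragment (the upper
~3 cm of the root is excised and mounted), not the plant's full root
length. Output tables state lengths in both pixels and micrometers.

## Segmentation model

The segmenter is a per-pixel classifier over a multiscale convolutional
feature bank. For each pixel of a patch, the features are the fluorescence
(green) channel plus its Gaussian smoothings and Gaussian-smoothed Sobel
gradient magnitudes at scales σ ∈ {1, 2, 4, 8, 16} px (11 features). Cell
walls are thin bright lines, so gradient energy at σ ≈ 2–8 px captures the
wall density that distinguishes periderm (dense, isotropic) from endodermis
(sparse, axial); σ = 16 px intensity context separates root interior from
background. All features are isotropic, which makes predictions equivariant
under the eight dihedral patch symmetries by construction (the augmentation
transforms are still provided for pipelines that want them).

The classifier head is a small MLP (default one hidden layer of 64 units)
trained with Adam at initial learning rate 1e-4 for 40 epochs (defaults),
on a 60/20/20 train/validation/test split of the patches driven by a single
seed. The loss is the sum of per-pixel multiclass cross-entropy (computed
from raw logits) and a soft-Dice term, 1 − mean per-class soft Dice over
the non-background classes present; both terms are logged separately. After
every epoch the validation IoU (mean per-class intersection-over-union,
skipping classes absent from both masks, scoring 0 for classes absent from
exactly one) is recorded, and the weights of the best-validation-IoU epoch
become the trained model.

Two sampling choices matter on whole-slide data, where background dominates
by an order of magnitude: pixels are drawn from each training patch with a
fixed per-class quota (so pure-background patches contribute little), and
the pooled sample is capped per class at 3× the median class count.
Validation pixels are drawn uniformly so the validation IoU reflects the
real class mix.

IoU convention, empty classes: absent from both prediction and target →
skipped; absent from exactly one → 0 for that class.

## Postprocessing

Per slide, roots are the 8-connected components of the non-background mask;
components under `min_root_area` (default 5,000 px, a debris floor) are
dropped, and roots are numbered left to right by the position of their
hypocotyl end. Per root:

1. The mask is projected onto the centerline: a centerline position is
   periderm iff the non-background pixels nearest to it (its local
   cross-section) are majority periderm, ties counting as periderm.
2. Scanning from the hypocotyl end, consecutive periderm runs whose
   centerline gap is ≤ `bridge_max_gap` (default 150 px) are merged and the
   gap's endoderm pixels relabeled periderm. At the first larger gap, the
   periderm pixels of every distal run are relabeled endodermis. A gap of
   exactly 150 px is bridged (the threshold's strict-inequality phrasing
   leaves the boundary case open; bridging it is the config-exposed
   default). The operation is idempotent and leaves at most one run,
   anchored at the proximal end.
3. Interior non-periderm pockets fully enclosed by the root's periderm and
   strictly smaller than `hole_max` (default 20 px) are filled; a hole of
   exactly 20 px is kept.

Gap distances are measured as arc length **along the centerline**, not as
straight-line distance between blob boundaries, because the trait itself is
length along the root.

## Centerline and lengths

The centerline is the morphological skeleton of the root region pruned to
its single longest geodesic (double Dijkstra sweep over the skeleton graph
with 1/√2 edge weights; deterministic lexicographic tie-breaks), which
removes lateral-root stubs and skeleton spurs. Two corrections make the
arc length quantitative:

* **End extension.** Thinning stops about half the root width short of a
  blunt root end; each centerline end is extended along its local direction
  until it leaves the region.
* **Staircase smoothing.** An 8-connected pixel path overestimates the
  length of the smooth curve it traces by a few percent at oblique
  orientations; a 5-px moving average of the coordinates removes the bias.
  On generated roots ≥ 40 px wide the recovered lengths are within ~0.5%
  of the analytic truth (the stated guarantee is 2%).

Whole-root length is the arc length of the full (smoothed) centerline;
periderm length is the arc length of the sub-path spanned by the single
post-bridging periderm run — bridged gaps therefore count toward periderm
length, which follows from treating small gaps as segmentation noise in a
contiguous tissue. Micrometer conversion is `px × known_distance /
pixel_distance` with the Fiji-style calibration (defaults 0.5299 px,
1.00 µm); anisotropic pixels are rejected rather than silently handled.

## Quality control

For each root the distal endpoint of the periderm run is the
periderm-to-endodermis transition point. A square window of ±1,500 px
(config-exposed) around it is cropped from the original image and from the
class-colored segmentation along both slide axes (the crop does not follow
the root axis — at these window sizes the difference is immaterial and the
axis-aligned crop is deterministic), stacked vertically, and written as
`<slide>_root<k>_qc.png`. A human lists the (slide, root) pairs to keep in
`selected_roots.txt`; applying the selection filters the periderm tables
into the `*_after_QC_*` CSVs. Whole-root tables are not filtered — QC
targets the periderm transition, which does not invalidate the whole-root
length. QC never alters masks or measurements.

## Synthetic data: what it emulates, what it does not

Each synthetic root is a sinusoidally perturbed vertical curve swept with a
constant width; the hypocotyl-proximal `periderm_fraction` of its arc
length is labeled periderm, the rest endodermis; ends are cut flat (the
mounted fragment is scissor-cut). Texture: a jittered Voronoi net of small
cells (~14 px) with bright walls in the periderm zone, a sparse grid of
long rectangular cells (~90 × 20 px) in the endodermis zone, a bright
suberized outline, optional lateral-root stubs, all rendered in a
green-dominant palette and degraded with Gaussian blur (σ 1.5 px) and
additive sensor noise (σ 8 intensity levels) — the mask is never degraded.
Slides hold up to six non-overlapping roots, hypocotyls toward the top
edge; default canvas 7,000 × 5,400 px ("half scale") with the full
14,000 × 10,800 px size behind a flag. Root parameter ranges (lengths
~0.55–0.9 of canvas height, widths 50–70 px, periderm fractions
0.25–0.60, 0–2 lateral stubs) emulate the natural variation between roots
on one slide. Ground truth is analytic: per-root centerline polylines and
arc lengths from the generating curve, plus a defect planter
(`corrupt_mask`) that relabels exact gap spans and punches exact holes for
the postprocessing rule tests.

What the generator does **not** model: staining variability and understained
roots, optical vignetting and stitching seams, out-of-focus blur gradients,
touching or crossing roots, root hairs, and genotype-dependent cell-size
changes. Passing the synthetic study therefore shows that the pipeline's
geometry, rules and training loop are correct and that the segmenter can
exploit cell-shape statistics; it does not certify accuracy on any
particular microscope's real images, for which the segmenter would be
retrained on annotated slides exactly as it is trained here on synthetic
ones.

## Scaled-down study design

The package's own reference study (run by `scripts/acceptance.py` and the
acceptance tests) trains on five half-scale slides — 210 patches of
1,024 px, 30 epochs — and evaluates on one held-out six-root slide. These
sizes were chosen as the smallest round numbers that keep the training set
above 200 patches and the evaluation at a full slide's six roots; at this
scale the held-out periderm IoU is ≈ 0.98 and the median absolute relative
error of recovered periderm lengths ≈ 0.2% (guarantees: median ≤ 10%
through the model path, ≤ 2% measuring the truth mask directly).

## Numerical choices and degenerate inputs

* Splits: sizes are (round(0.6 n), round(0.2 n), remainder); n = 1,471
  gives 883/294/294. Fewer than 3 patches is an error.
* Precision/recall with a zero denominator return 0 (logged); F1(0, 0) = 0.
* Rasterization fills a polygon at pixel centers by the even-odd rule;
  later polygons overwrite earlier ones (last drawn wins, matching
  interactive annotation); self-intersecting polygons fill even-odd with a
  warning. Unknown class labels are rejected listing the accepted ones.
* 16-bit images are linearly min-max rescaled to 8-bit with a warning;
  grayscale is replicated to 3 channels.
* Tiling is a ceiling cover: ⌈extent / (patch − overlap)⌉ patches per axis
  (with a guard that the last patch reaches the edge), zero-padded at the
  right/bottom; stitching discards padding; at overlap > 0 the later
  row-major patch wins, keeping masks integer-exact.
* Regions whose skeleton has ≤ 2 pixels get a single-point centerline of
  length 0. An empty slide mask yields an empty root list, not an error.
* Determinism: every stochastic step (splits, pixel sampling, MLP
  initialization, generator output) is a pure function of its seed;
  repeated runs give identical CSVs.

## Known limitations

* The segmenter is a texture classifier without long-range context; on real
  slides with staining artifacts it will need the QC step more than a deep
  encoder-decoder would, and per-microscope retraining is expected.
* Lateral roots are detected as a class and excluded from the main axis,
  but their own lengths are not measured, and the thin stubs are the
  class with the weakest IoU.
* Roots that touch or cross are not split; they surface as a root-count
  mismatch warning and should be rejected in QC (slides should carry at
  most six well-spaced roots).
* The periderm-to-root-length ratio is deliberately not a headline output;
  it can be derived from the two tables.
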