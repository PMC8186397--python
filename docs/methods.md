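# Methods

## Problem setting

A TRAP-stained osteoclast culture well is imaged as one large RGB
micrograph. The biological endpoints are, per well and per cell type, the
number of cells and the fraction of the culture surface they cover. Cell
types are defined by nucleus count at annotation time: preosteoclasts
(TRAP⁺, 1–2 nuclei), type I osteoclasts (3–14), type II osteoclasts (≥15),
and ghost cells — vanished cells recognizable only by a faint silhouette.
The ≥3-nuclei threshold is the standard *in vitro* osteoclast definition;
`classify_cell_type` encodes exactly this partition and rejects anucleate
TRAP⁺ annotations.

Annotation follows the region protocol: each well is split into a 4×4 grid
of equally sized regions (remainder pixels going to the last row/column)
annotated as separate images, with one polygon per cell in LabelMe-dialect
JSON. Region files carry the standard LabelMe keys plus `wellId`,
`regionId`, `regionOffset`, and a per-shape `n_nuclei` — a compatible
superset, since plain LabelMe has no slot for nucleus counts. Coordinates
are 0-based pixels, origin top-left; boxes are half-open.

## Detection model

The detector is a single-shot multibox network. A stride-2 convolutional
backbone produces feature maps at 1/8, 1/16, 1/32 and 1/64 of the input;
a classification head and a localization head (3×3 convs) sit on each of
the four levels. Four levels — rather than the six of generic SSD — drop
the coarsest anchor scales: no cell approaches the size of a whole patch,
and the anchors must only span cell diameters of 51–383 μm. Whether a
given configuration actually covers that physical range is a checkable
property (`DetectorConfig.anchor_physical_range`) parameterized by
`um_per_input_px`; the pixel scale is never silently assumed.

Anchors are squares (ground-truth boxes are tightest squares by
construction, see below) at three geometric sub-scales per level (step
2^{1/3}, per-level base scales 0.07–0.56 of the input, doubling per
level), centered on every feature-map cell and clipped to the unit square.
Matching is the standard two-stage SSD rule: every ground-truth box first
claims its best-IoU anchor (so no object goes unmatched), then every
anchor at IoU ≥ `match_iou` to some ground truth becomes positive. Boxes
are encoded against anchors as center offsets and log sizes with the usual
variances (0.1, 0.2). The loss is `(L_conf + L_loc)/N_pos`: softmax
cross-entropy over positives plus the hardest negatives (capped at 3·N_pos,
chosen by background cross-entropy), and smooth-L1 on the positive
offsets. Inference decodes all anchors, drops scores below
`confidence_threshold` (0.5), and applies class-wise greedy NMS at IoU
0.45.

Polygons are converted to the **tightest square** containing the cell:
side = ceil(max extent), centered on the polygon's extent, shifted (never
shrunk) to fit the image; squareness yields to containment only when the
side exceeds an image dimension. Squares make the box distribution
aspect-free, which is why square anchors suffice.

### Backbone profiles and training

The backbone is pluggable. Two named profiles exist:

* **full-scale profile** — input 300, VGG16-scale channels (64…512), feature
  maps 38², 19², 10², 5²; training 120,000 iterations, batch 32, Adam,
  learning rate 1e-5, constant. This is the full-resolution configuration
  for users with a pretrained backbone and days of compute; it is
  constructed and unit-tested but never trained in this repository's test
  runs.
* **desk profile** — input 160, small batch-normalized backbone (channels
  24–64, extra 3×3 convs in the two middle blocks), feature maps 20²,
  10², 5², 3². Training: 2,000 iterations, batch 8,
  Adam at 1e-3 with 50-iteration warmup and a /10 step at 75% of the run.
  The higher learning rate and batch normalization are what make a
  *randomly initialized* network trainable in 2,000 iterations; the full-scale
  profile's 1e-5 is tied to starting from pretrained weights.

All randomness flows from one seed; training is run-to-run reproducible to
float tolerance. NaN loss aborts with a diagnostic; gradients are clipped
at global norm 10. Checkpoints are single `.npz` files embedding the
weights, the batch-norm running statistics, the full `DetectorConfig`, and
the package version.

## Patch amplification

Annotating one culture takes hours, so only ~10 annotated wells are
realistic. Because cells are small relative to the well, any sub-window is
itself a valid training image: training samples are random patches with
width and height drawn independently and uniformly from 10–15% of the well
dimensions and position uniform over valid top-left corners. For a
1000×1000 well this gives ≈2.0·10⁹ distinct `(w, h, x, y)` patches
(`count_patch_space` computes the exact sum; the closed form is verified
against exhaustive enumeration). Ground-truth boxes are clipped to the
patch and kept iff ≥25% of their area survives — slivers of cells cut by
the patch border teach nothing, while genuinely split cells remain.
Patches are resized (bilinear) to the detector input; the aspect
distortion from independently drawn width and height is accepted, as is
standard for single-shot detectors.

Augmentation: photometric jitter (brightness ±0.08 on 0–1 intensity, hue
±0.03 on the hue circle, saturation ×0.85–1.15), vertical flips (p=0.5),
and rotations by 0/90/180/270°. Photometry never touches boxes; geometry
remaps them exactly; labels never change. The random stream is split per
stage (positions vs augmentation) so toggling augmentation does not
perturb which patches are sampled.

## Whole-well inference

A well is divided into a fixed 8×8 grid of non-overlapping tiles (64
patches, mirroring the patch scale of training); the model runs on each
tile and the outputs, translated by tile origin, are simply concatenated.
No cross-tile merging is done by default — cells straddling tile borders
may be detected twice or partially, an error mode that `split_cell_audit`
quantifies (count of ground-truth squares intersecting ≥2 tiles) and that
duplicates cannot corrupt area estimates (union semantics below). An
optional `cross_tile_nms` flag dedups across borders for callers who want
it; it is off by default to keep the plain-union scheme.

## Quantification and agreement

Counts are exact per-class tallies; preosteoclasts and ghosts are never
pooled into osteoclast counts. Covered area is the area of the geometric
**union** of shapes, computed by rasterizing at native resolution —
adding a duplicate or contained shape cannot change it, which is precisely
why a double-boxed split cell is harmless for area. Annotation-side area
uses polygons; detection-side area uses boxes; every report states its
basis. Physical areas use μm² = px²·(μm/px)², with the pixel scale a
required input.

Agreement between sources (annotators, model) is the Pearson correlation
of per-region measurement vectors. Detections are assigned to the region
containing their box center, so no cell is double counted across regions;
regions where *all* sources report zero are dropped (mirroring the
protocol of discarding cell-free regions), and zero-variance vectors raise
rather than silently returning 0. `agreement_matrix` emits the symmetric
pairwise matrix; `residual_normality` runs the D'Agostino–Pearson K²
omnibus test on the residuals of the least-squares fit of one source on
another (α = 0.05, n ≥ 8; exactly linear data passes by definition).

## Synthetic cultures

No public annotated TRAP-culture image set exists, so the
`synthetic_culture` module renders seeded wells with exact ground truth.
What it emulates: magenta/purple TRAP⁺ cells (HSV hue 0.83–0.93) of four
types on a pale noisy background with gentle rim-ward illumination
falloff; nucleus counts drawn per class (uniform on {1,2}, {3..14},
{15..40}) and rendered as dark ~9 μm dots inside the cell; class-scaled
diameter distributions inside the 51–383 μm envelope; ghost cells as
near-background silhouettes with a faint outline (making them genuinely
hard — low ghost agreement is reproduced as a property, not a bug); a
radial density gradient (cells denser toward the well center, as in real
cultures); and cell shapes as smoothed random-star polygons (low-order
Fourier noise on an ellipse) so that box conversion, IoU and rasterization
paths face irregular geometry.

Density defaults are expressed per annotation region. The full-scale
default is 66.4 cells per 250 px region at 7 μm/px (the average regional
cell load of such assays); the desk configuration keeps the same areal
density at 512 px wells. Placement is largest-first rejection sampling
under a circle-proxy overlap constraint (centre distance ≥
(1−`max_overlap`)·(r₁+r₂)); an unplaceable cell raises a density-infeasible
error after bounded attempts. Each cell is assigned to the region holding
the largest piece of its polygon and the stored polygon is clipped to that
region — exactly what a human annotating per-region images produces.
μm/px for real ×4 micrographs is not standardized; the default 7.0 (a
1000 px well ≈ a 7 mm culture well) is documented, configurable, and
never silently assumed by the CLI.

The **easy profile** used by the scaled-down end-to-end runs is the
deliberately gentler variant: sparser lawn (9 cells/region at 512 px),
stronger stain contrast (×1.25), near-zero overlap, and per-class diameter
ranges that do not overlap between classes. `generate_difficulty_suite`
then produces harder levels by turning exactly three knobs: contrast down,
density up, allowed overlap up.

What the generator does *not* model: optical vignetting and chromatic
artifacts of a specific microscope, partial staining within a cell,
touching/fused cell clumps with shared boundaries, debris, and the
circular well rim. Passing tests on synthetic wells therefore demonstrate
that the pipeline's machinery is correct and that the detector can learn
and quantify cultures with these statistics — not that a model trained
here transfers to any particular laboratory's images, which require
training on their own annotations.

## Scaled-down study design

The repository's end-to-end check mirrors the full study's design at desk
scale: generate 12 easy-profile wells from one seed, train the desk
profile on 10, run tiled inference on the 2 held-out wells, and correlate
model vs ground-truth per-region type-I counts and areas over the 32
held-out regions. The easy profile keeps the full-scale image geometry
(1000 px wells, so cells have the intended size relative to regions and
tiles); the scaled-down parts are the training budget (2,000 iterations,
batch 8, small backbone) and the halved lawn density. Per-region type-I
counts average ≈13, and the correlation is computed over both held-out
wells' regions pooled.

## Numerical choices and edge cases

* Box codec round trips to <10⁻⁶ relative error; decode clamps log-size
  offsets at 12 before exponentiation.
* NMS sorts stably by descending score; ties in matching go to the lowest
  anchor index — both for exact reproducibility.
* Max-pool backward splits gradient equally among tied maxima, keeping the
  adjoint exact.
* With zero positives the multibox loss has no localization term and runs
  its confidence term over at most `neg_pos_ratio` hardest negatives.
* Degenerate polygons (zero extent) get a minimum 1 px square;
  sub-pixel ground-truth slivers (<1 px² after region clipping) are
  dropped by the generator.
* Empty detection lists are legal everywhere; zero-variance agreement
  vectors raise `AgreementError`.

## Known limitations

* The naive tile union double counts border-straddling cells (and can
  miss cells whose per-tile fragments are too small to fire). The effect
  grows as tiles shrink relative to cells: on the 512 px quick-run
  configuration tiles are only ~3 type-I diameters wide, roughly doubling
  the split-cell incidence of the full 1000 px geometry. Count errors can
  only inflate from duplicates; union areas are unaffected by them.
* Ghost-cell detection is poor by design of the stain (and of the
  renderer); ghost counts should be treated as indicative.
* The numpy network trains a small backbone from scratch; it is not a
  substitute for a pretrained VGG16 at full resolution when real,
  full-size micrographs are available.
* Pixel-level instance segmentation from the polygons is out of scope.
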