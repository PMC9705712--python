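# Methods

This note documents the models, procedures and numerical choices behind
`seedtax`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data can and cannot tell you.

## The problem

Seed shape and seed-coat sculpture are the primary diagnostic characters
for several aquatic plant genera whose vegetative parts are highly
plastic.  The pipeline compares two identification routes on single-seed
electron-microscope-style images:

* a **morphometric route** — six hand-measurable variables (projected
  area, outline perimeter, the two sides of the minimum-area rotated
  bounding rectangle, the bend angle of the seed axis, and the pit count
  on the seed coat) classified with Gaussian discriminants (LDA/QDA) and
  a random decision forest (RDF);
* an **image route** — a small convolutional network fed the standardized
  128 x 128 seed image directly.

Because no real image set is bundled, every stage is exercised against a
synthetic generator that provides analytic ground truth.

## Synthetic seed model

A seed is a **bent capsule**: the set of points within `w/2` of a
centerline arc of length `l - w`, where `l` is the nominal seed length
and `w` its width.  Bending is parameterized by the bend angle `beta` in
(0, 180] degrees — the angle subtended at the arc midpoint by the two
centerline endpoints (inscribed-angle geometry): 180 means straight,
90 a semicircular U.  Bending is an isometry of the cross-section, so
area and perimeter have closed forms independent of `beta`:

    area = (l - w) w + pi (w/2)^2        perimeter = 2 (l - w) + pi w

and the minimum-area rotated rectangle is computed geometrically from the
buffered arc polygon.  The bend is constrained by
`(180 - beta) <= (l - w)/w` (in radian measure): beyond that the inner
arc radius goes negative and the capsule would self-intersect, so
generated and sampled bends are clamped to that floor.

Rendered frames are 1024 x 768 8-bit grayscale: uniform background
(default gray 40) with Gaussian noise (SD 5), the seed body at gray 185,
debris ellipses, a bottom metadata bar (dark strip with bright
glyph-like rectangles), and seed-coat pits drawn as non-overlapping
darker disks (default radius 4 px, contrast 25% of the seed/background
difference) placed by rejection sampling inside the eroded seed body.
The pit count, not just the density, is recorded as ground truth.

Class structure: a phenotype library places 12 class geometries around a
common base (length 430 px, width 175 px, bend 150 deg, 0.45 pits per
1000 px^2, within-class CV 4%), displaced along class-specific random
directions with amplitude proportional to a `separation` knob; 0 makes
all classes identical, 2 makes them nearly disjoint.  A small
per-population jitter (±3% of the class means) emulates between-population
variation within a taxon.  The bundled study layout mirrors the field
design this emulates: 12 taxa in 28 populations with 24–55 images each,
1299 frames in total.

When `allow_contact` is set, one debris blob is deliberately placed
2–2.8 px from the seed boundary: close enough that one dilation step
bridges the gap (the contact-rejection rule fires) yet far enough that
thresholding still sees two components.  Genuinely overlapping objects
would merge into a single thresholded component and are undetectable by
any post-hoc rule, which is exactly why such frames are excluded rather
than repaired.

**What the generator does not emulate:** real SEM shading and charging
artifacts, micro-relief pit texture (pits here are flat disks),
off-focus blur, seed-on-seed occlusion, and magnification metadata.
Passing tests therefore demonstrate internal consistency of the
pipeline — segmentation recovering the rendered mask, measurements
recovering the rendered geometry, classifiers recovering the planted
class structure — not field performance on real micrographs.

## Preprocessing

1. **Segmentation** — global Otsu threshold; the side holding the
   majority of border pixels is background, which makes the stage
   invariant to contrast polarity; one 8-connected morphological opening
   removes speckle.  (A pretrained deep segmenter could be slotted in
   here; the classical route keeps the pipeline deterministic and
   dependency-light, behind the same mask contract.)
2. **Contact check** — on the raw mask, the largest component is dilated
   once (8-connectivity); if it then touches any other component the
   frame is excluded with reason `contact`.  Frames whose objects are
   separated by ≥ 3 px always pass.
3. **Cleaning** — components intersecting the metadata-bar strip
   (default: bottom 60 px) are removed, then components smaller than
   `min_area_frac` (default 0.05) of the largest, then all but the most
   prominent component.  Ties on area break to the component whose
   centroid comes first in row-major order.
4. **Crop/pad** — the mask bounding box grown by a 4 px margin, padded
   to a centered square with the median border gray.
5. **Standardize** — bilinear rescale to 128 x 128, grays mapped to
   [0, 1].  Coordinates are 0-based row-major with half-open boxes.

## Morphometrics

* **Area**: foreground pixel count.
* **Perimeter**: length of the marching-squares sub-pixel contour after
  a 5-point wrap-around moving average; the raw contour staircases along
  rasterized smooth boundaries and overestimates length by up to ~7%,
  while the smoothed polygon is within ~1% on disks and capsules and ~2%
  on rectangles.
* **Rectangle a/b**: side lengths of the shapely minimum rotated
  rectangle of the outer contour polygon.
* **Bend angle**: the medial axis (EDT ridge) is traced to its longest
  path.  Plain topological thinning bows several pixels inside the true
  centerline on strongly curved shapes and biased the angle by up to 8
  degrees, hence the medial axis; its thinning-order tie-break is seeded
  so the measurement is deterministic.  Blob-like masks whose axis is
  shorter than half the local half-width are rejected.  Tip branches whose inscribed-disk
  radius collapses below 85% of the path median are trimmed, and each
  end is extended along its local tangent to the cap center (march to
  the mask tip, pull back by the local half-width).  The reported angle
  is ∠E1–M–E2 at the arc-length midpoint M.  Masks without two
  endpoints, or with side branches beyond the cap scale, raise an
  ambiguous-shape error.
* **Pit count**: inside the mask eroded by 3 px, pixels of the
  1-px-Gaussian-smoothed image darker than the interior median by 10
  gray levels are grouped 8-connectedly; blobs of equivalent radius
  ≥ 2 px count.  The light smoothing makes the threshold a ~6-sigma
  event under the default noise, so the count is stable (and exact on
  the generator's pits).

Verified invariances: quarter-turn rotation leaves all six variables
unchanged (angle within 5 deg, lengths within 3%); rescaling by `s`
scales area by `s^2` and lengths by `s`.  Against generator truth the
defaults recover area within 2%, rectangle sides within 3%, bend within
10 deg, and the pit count exactly.

## Augmentation

Exactly 86 deterministic variants per training image, in fixed order:
5 brightness/contrast (gains 0.8/0.9/1.1/1.2 plus a 2–98 percentile
stretch), 6 sharpen (unsharp masking at strengths 0.5 and 1.0 × three
flip states), 12 blur (Gaussian sigma 0.5/1/1.5/2 × three flip states),
61 rotation/flip combinations, and 2 plain flips.  The rotation family
is 23 pure rotations (15–345 deg in 15-deg steps) plus rotations
0–270 deg of the horizontally and of the vertically flipped image (19
each); the decomposition of 61 into rotations-with-flips is not unique,
so this count-exact choice is a documented convention, overridable
through `AugmentationPlan`.  Rotations are bilinear with border-median
fill; all outputs re-clip to [0, 1].  Images flagged as test-partition
members are refused (no augmentation leakage by construction).

## Classification harness

Feature tables hold the six variables plus class and population labels.
Each repetition draws a fresh per-class split (test size
`ceil(0.25 n_k)` per class), refits from scratch, and scores the test
partition; nothing carries over between repetitions (seed ladder
`base_seed + r`).

LDA/QDA score with the Gaussian discriminant
`delta_k(x) = -0.5 log|S_k| - 0.5 (x-mu_k)' S_k^{-1} (x-mu_k) + log pi_k`
(pooled S for LDA, per-class unbiased S_k for QDA) with a ridge of
1e-6 × the mean feature second moment added always, so QDA never fails
on small classes.  Posteriors are normalized exponentials of the scores;
tests verify them against brute-force multivariate-normal densities to
1e-9.  RDF is a 100-tree random forest (bootstrap, sqrt-p feature
subsetting, unlimited depth).

Aggregation: accuracies summarized as min/max/mean/median/sample-SD in
percent; confusion matrices pooled over repetitions then row-normalized
to percent (per-repetition row-normalized averaging is available as a
config option — with equal per-class test sizes the two nearly
coincide); permutation importance is the mean accuracy drop over 10
within-column shuffles on the test partition; ROC/AUC is one-vs-rest
from class posteriors with trapezoid integration.

## Convolutional classifier

Architecture: four conv(3x3, same padding) → batch-norm → ReLU →
max-pool(2x2) stages with 16/32/64/128 filters; flatten (8·8·128 =
8192); dense 8 → dense 232, each followed by dropout (rate 0.25); dense
12 with softmax.  The realized trainable parameter count is **168,060**
(conv 97,152 + BN 480 + dense 70,428).  The two dense widths are a
package choice — 8 and 232 land the parameter budget in the intended
"lightweight" regime — and the count is printed in every run report
rather than asserted, since nearby budgets are achievable with other
width pairs.

The narrow dense stages use a leaky rectifier (negative slope 0.05):
with a plain ReLU the 8-unit bottleneck loses most of its units to the
dead-ReLU regime within a few Adam steps and training stalls; the leaky
slope keeps gradients flowing without changing any parameter count.
Convolutional stages keep plain ReLU (batch-norm prevents the same
pathology there).

Training: Adam (beta 0.9/0.999) at learning rate 1e-4 with per-epoch
decay `lr/(1 + 1e-4 · epoch)`, up to 4500 epochs with early stopping
(patience 50, min-delta 1e-4) on the monitored loss — validation loss
when a held-out set is supplied, else training loss.  The loss is
categorical cross-entropy by default; a `binary` mode (mean per-output
binary cross-entropy on the softmax vector) is available for protocol
fidelity with small-data recipes that train one-hot outputs that way.
Splits for the image route are global (not per-class) 75/25 of original
images — 1299 frames give 974 train / 325 test — and augmentation, when
enabled, expands only the training partition (86 variants per original;
974 originals → 83,764).

The implementation is plain numpy (im2col convolutions, stride-trick
pooling, hand-written backprop verified against numerical gradients in
the test suite), single-threaded and deterministic given the seeds.

**Desk-scale preset.** Full-protocol training (86× augmentation,
thousands of epochs) is not meaningful on one CPU core, so demonstration
runs, tests and the acceptance script use a documented preset: learning
rate 1e-3, batch size 32, 15 epochs, dropout disabled, on a few hundred
original images at input resolution 128 x 128 (the resolution is kept;
the budget is scaled through images, epochs and the augmentation
family).  Instead of the 86-variant plan, the training partition is
expanded with its exact quarter-turn rotations (interpolation-free
`rot90` copies): seeds land at arbitrary orientations, and without some
rotation augmentation a network trained on a few hundred images
memorizes orientations instead of shapes (train 0.97 / test 0.33 in our
ablation); the quarter-turn subset restores orientation robustness at
4x rather than 86x the epoch cost, and at this data scale it also takes
over the regularizing role of dropout.

The separable demonstration classes come from
`synthetic.image_separable_phenotypes`: a 12-point aspect-ratio x
bend-angle grid rather than the generic phenotype library, because
standardization erases absolute size — classes differing mainly in
length are trivially separable on measured area yet indistinguishable
in the normalized image.  Grid spacing is at least ~5 within-class
standard deviations in each varied character.  Under this preset the
network overfits 24 images to 100% training accuracy (dropout off, as
usual for a capacity check), sits at chance (~1/12) untrained on a
balanced set, and exceeds 80% held-out accuracy on 20 images/class
(measured: 92% at seed 0) within the 30-epoch cap.

## End-to-end comparison

The report stage ranks methods by mean accuracy (descending, ties
alphabetical) in the classic Min/Max/Mean/Median/SD layout (percent to 1
decimal, SD to 2), with pooled row-percent confusion matrices (rows =
true class) and per-class AUCs alongside; every number is recomputable
from the persisted per-repetition artifacts.  The numbered scripts under
`analysis/` drive the stages at desk scale and write their tables under
`results/`.

## Known limitations

* The bend-angle estimator assumes a single-axis, capsule-like shape;
  branched or blob-like masks are rejected rather than guessed.
* Pit counting assumes pits are darker than the coat and at least ~2 px
  in radius after smoothing; shallow micro-relief would be missed.
* The contact check cannot flag objects that overlap the seed in the
  thresholded image (they merge into one component); such frames are
  mis-segmented rather than excluded, as with any single-object pipeline.
* Synthetic class structure is far cleaner than real congeneric seed
  variation; absolute accuracies here say nothing about real taxa.
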