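# Methods

This note documents the models and procedures implemented in `ambbem`,
the assumptions they make, the synthetic data they are validated on, and
the numerical choices a user may want to audit.

## 1. The extraction model

The pipeline assumes a pre-windowed 8-bit axial head-CT slice in which
bone is the brightest tissue class, within 15 gray levels of the slice
maximum, and everything else sits at least 20 levels below the maximum.
Both offsets are fixed constants of the method, not tuned per slice; they
deliberately over-reach a little to absorb window-width/level variation.
A slice whose maximum is below 200 (no bone-range intensities at all) or
whose thresholded skull covers less than 0.1 % of the pixels is rejected
as unsegmentable rather than silently producing an empty mask.

Hole filling treats the background as 4-connected (foreground effectively
8-connected), so a diagonally tight ring still encloses its interior and
cannot leak at corners.  Foreground connectivity is 8 everywhere else
(component counting, region growing, top-k extraction).

### Closure loop

The filled-area fraction `q = (S_i − S_e1)/S_i` equals `1 − S_e1/S_i`, so
it is strictly increasing in the mask area and lies in `[0, 1)` whenever
the skull is nonempty.  The loop:

* fills the skull once and tests `q > TV`;
* on failure, closes the skull with a disk structuring element of radius
  equal to the cycle index (1, 2, …, 5) and refills.  The radius schedule
  is the natural reading of a structuring element that "grows by one";
  a radius-r disk bridges ring breaks up to about `2r` pixels wide;
* on a basis-cranii slice the first failed test instead reassigns
  `TV := 0.2485` — once — and re-tests before any closing.  The trace
  records the reassignment by updating the threshold of the current
  record, keeping the trace length at `max_cycles + 1` or less;
* after 5 cycles it returns the best mask so far.  The cap guards against
  slices whose *complete* fill still scores below `TV`; running more
  cycles would only dilate bone into soft tissue.

The loop deliberately reproduces a known failure mode rather than fixing
it: with several simultaneous gaps, closing one gap can push `q` past
`TV` while others remain open, losing a small brain area.

### The TV regression

`TV` predicts, per slice, roughly what the filled fraction of a complete
mask should be.  The model is ordinary least squares of the complete-mask
filled fraction on the skull-to-soft-tissue area ratio (soft-tissue area
= nonzero support of the skull-removed image).  The shipped default

```
TV = 0.9489 − 0.8277 · (skull area / soft-tissue area),   R = 0.96
```

was calibrated once on 142 gap-free phantoms from this package's
generator (`ambbem.calibration.calibrate_tv_model` reproduces the
coefficients; a regression test checks the round trip).  Predictions are
clamped to `[0.01, 0.99]`.  Users with real calibration data should refit
and pass their own `TVModel`.  At the basis cranii layer the covariate
leaves the calibration range and the linear extrapolation is unreliable —
that is exactly why the classifier-driven reassignment to the fixed
constant 0.2485 exists.

## 2. The slice classifier

Four classes: basis cranii, and one/two/three-plus brain regions.  The
class steers two decisions only — whether `TV` may be reassigned, and how
a multi-component mask 2 is re-segmented (region growing for
basis-cranii/single-region, keep-2 or keep-3 for the rest).  Basis-cranii
slices follow the region-growing path because their mask is a single
small area once filled.

**Improved ResNet50.**  Standard ResNet50 topology (7×7/2 stem, 3×3/2
max-pool, bottleneck stages of 3/4/6/3 blocks) with a CBAM block —
channel attention with a shared 2-layer MLP (reduction 16) over average-
and max-pooled descriptors, then spatial attention with a 7×7
convolution — inserted after the stem pooling, and one
squeeze-and-excitation block (reduction 16) appended after each of the
four stages.  Attention hyperparameters are the originals' defaults; SE
is applied per stage, the minimal reading of "one per bottleneck
section".  The head is global average pooling, a 4-way linear layer and
softmax.  Training uses cross-entropy with Adam at learning rate 0.001
and batch size 16 for up to 45 epochs, stopping early once the training
set is fit (accuracy 1.0, mean loss < 0.05).  Inputs are
bilinearly resized to 224×224, replicated to 3 channels and scaled to
[0, 1]; `ClassifierConfig.input_side` and `width` expose the input side
and a channel-width multiplier so the same topology can be trained at
reduced cost (the demonstration in the test suite trains the full-width
network at a 56-px input on 400 phantoms of side 128 — about four minutes
on one CPU core — and reaches ≥ 0.90 held-out accuracy; the architecture
is resolution-agnostic).

The network runs on `ambbem.nn`, a compact NumPy layer stack (im2col
convolution, batch norm, pooling, SE, CBAM, bottleneck, Adam) written for
this package; every backward pass is checked against central-difference
numerical gradients in the test suite.  Inference is CPU-only by
construction.

**Heuristic fallback.**  Thresholds the skull, closes it with a radius-4
disk (bridging any gap up to the generator's 5-px maximum), fills, and
inspects the interior: filled fraction < 0.35 → basis cranii; otherwise
the number of interior components with area ≥ 15 % of the largest gives
the region count.  The two cutoffs sit between well-separated modes of
the phantom population (basis fractions ≤ 0.31 vs ≥ 0.5; walled-off
non-brain remnants ≤ 10 % of the largest region vs real regions ≥ 25 %).
The heuristic exists so the deterministic pipeline never requires a
training run; both classifiers satisfy the same `classify` contract and
are interchangeable.

## 3. Seed selection and re-segmentation

The seed search scans rows bottom-up inside a midline band of half-width
`W/16` (32 px at 512); at the first row containing foreground it takes
the pixel nearest the midline, lifts it 5 rows, and if the lifted pixel
is background steps further up the same column.  The bottom-up direction
encodes an anatomical prior: the leftovers to be eliminated sit above the
brain parenchyma, and the scalp and bone below it have already been
removed.  If the band is empty the pipeline falls back to keeping the
largest component.  On a binary mask, region growing from the seed is
exactly the seed's connected component (verified against a brute-force
flood fill); ties in top-k area selection break toward the smaller
row-major first pixel.

The median filter (mask 2 and noise reduction) uses a 5×5 window with
edge replication; 3×3 left speckle at the phantom scales tested.  The
filter runs on the masked image, before binarization.

## 4. Evaluation metrics

The confusion matrix takes brain tissue as the positive class, rows =
truth, columns = prediction.  `mpa` and `miou` implement the method's
printed averaged forms exactly; note the MPA terms are precision-like
(`TP/(TP+FP)`), which differs from the textbook per-class recall — a
clearly named `mpa_recall` is provided for users who want the
conventional quantity, and the two are never silently swapped.  Boundary
F1 extracts boundaries as foreground pixels with any 8-neighbor
background (image border counts as background), matches them within
`0.0075·√(H²+W²)` pixels (unrounded) via Euclidean distance transforms,
and averages the foreground and background F1.  `ass` is slices per
second; the batch runner can repeat the timing (e.g. five times) and
average.

## 5. The phantom generator

Phantoms emulate what the pipeline exploits and nothing more: geometry is
elliptical-annulus-based, not anatomically deformable, because the method
only uses topology (a closed or nearly closed bright ring enclosing
darker tissue) and first-order intensity statistics.

* Tissue intensities are Gaussian per pixel, clipped to disjoint bands:
  skull 250±3 (clipped ≥ 243, a few pixels pinned at 255 so the slice
  maximum is anchored), brain 110±12 (the main soft-tissue peak),
  hematoma 190±6 (the secondary peak, included in the truth mask), scalp
  100±8 — within 30 levels of brain, as on real slices — pillow 140±6.
  No beam hardening, streaks, or partial-volume effects.
* Multi-region slices use bone septa (≥ 5 px thick) spanning the interior,
  mimicking bone-separated brain areas near the sella turcica; region
  areas are ≥ 25 % of the largest so the classes are separable.
* Basis-cranii slices have a bone-dominated interior with a central brain
  area of 25–31 % of the filled outline — just above the 0.2485 constant,
  as the TV logic requires — and a doubled soft-tissue ring.
* Skull gaps are straight channels of constant width carved along an
  outward ray; strict sub-half-width rasterization keeps the opening at
  most the stated width.  Gaps avoid septum junctions so a break is never
  plugged by other bone.
* An optional walled-off soft-tissue pocket near the vertex (enclosed by
  a bone rim tied to the inner table) produces the multi-component mask 2
  that exercises the region-growing path.

Everything is deterministic given the spec seed; dataset generation uses
largest-remainder rounding for class proportions and derives per-sample
seeds from the master seed.

**What passing on phantoms does and does not show.**  The phantoms prove
the mechanics: thresholds select the intended tissue, gaps of stated
width close within the observed cycle budget, the classifier separates
the four layouts, the refinement keeps exactly the intended components,
and the metrics agree with brute-force oracles.  They cannot certify
clinical accuracy: real slices have anatomical boundary detail,
partial-volume gradients, lesions beyond a single bright blob, and
windowing variation that the generator does not model.

## 6. Batch sizes and runtime choices

The shipped measurements run at the sizes a single CPU core handles in
minutes: the closure-cycle batch uses 100 phantoms at the native 512-px
slice size (the thinnest rings at smaller sizes put 5-px gaps at the
discrete closing boundary, an artifact of scale, not of the method); the
end-to-end recovery batch uses 200 phantoms at 256 px, where the ~1-px
median-filter boundary erosion costs well under the 0.95 MIoU margin;
classifier training uses 400 slices at 128 px with a 56-px input.  The
TV calibration uses 142 phantoms at 256 px.

## 7. Known limitations

* The multi-gap failure mode described above is reproduced by design.
* Eq-style fixed offsets (15/20) assume 8-bit pre-windowed input; raw
  DICOM (including windowing) is out of scope.
* The seed search assumes remnants lie above the parenchyma; a below-brain
  remnant on a single-region slice would capture the seed.
* `mpa`'s printed form rewards over-segmentation less than recall-based
  pixel accuracy would; use `mpa_recall` for cross-study comparisons.
* The NumPy CNN backend is single-threaded BLAS-bound; it trains the
  full-width network at reduced resolution in minutes but is not meant
  for 224-px, large-corpus training.
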