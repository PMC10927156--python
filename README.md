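# ambbem — adaptive mask-based brain extraction for head CT

`ambbem` strips the skull, scalp, pillow and other non-brain structures from
single axial head-CT slices, leaving only brain tissue.  It is aimed at
people building intracranial-lesion pipelines (hemorrhage detection, brain
volumetry) who need a brain mask that is fast, interpretable, and runs on a
CPU — the regime where classical image processing beats a full
segmentation network on speed while matching it on accuracy for this task.

## The method

A head-CT slice `E` has a characteristic intensity structure: bone is the
brightest tissue (near the slice maximum), intracranial hematoma comes
second, and brain parenchyma and extracranial soft tissue sit far below,
close to each other.  The pipeline exploits this:

1. **Threshold segmentation.** The skull image and the skull-free image
   are cut from the slice maximum:

   * `e1(i,j) = 1` iff `E(i,j) ≥ max(E) − 15` (skull),
   * `e2(i,j) = E(i,j)` iff `1 ≤ E(i,j) ≤ max(E) − 20`, else 0.

2. **Fill detection and skull closure.** Filling the enclosed hole of `e1`
   gives mask 1 — but only if the bone ring is closed.  Fill success is
   measured by the filled-area fraction

   `q = (S_i − S_e1) / S_i`

   (`S_i` mask area after cycle `i`, `S_e1` skull area).  While `q ≤ TV`,
   the skull is repaired by morphological closing with a disk whose radius
   grows by one each cycle (at most 5 cycles), then refilled.  The
   acceptance threshold `TV` is predicted per slice by a linear regression
   on the skull-to-soft-tissue area ratio; on **basis cranii** slices —
   skull base, small brain area, where that regression extrapolates
   poorly — `TV` is reassigned once to the fixed constant **0.2485**, the
   mean brain fraction of the complete mask at that level.

3. **Slice classification.** A 4-way classifier labels the slice basis
   cranii / one / two / three-plus brain regions.  Two interchangeable
   implementations ship: an **improved ResNet50** (CBAM attention after
   the stem, squeeze-and-excitation after each of the four bottleneck
   stages, softmax over 4 classes, trained with Adam, lr 0.001, batch 16,
   up to 45 epochs) built on a small NumPy CNN backend, and a
   deterministic morphology heuristic that needs no training.

4. **Mask re-segmentation.** The masked slice is median-filtered and
   binarized to mask 2.  One connected region → done.  More → the class
   decides: single-region slices keep the component grown from a seed
   found by scanning the image midline bottom-up (then lifted 5 rows);
   multi-region slices keep the *k* largest components (k = 2 or 3).

5. The final mask multiplies the original slice to yield the extracted
   brain.

Segmentation quality is scored by MPA `= ½(TP/(TP+FP) + TN/(TN+FN))`,
MIoU `= ½(TP/(TP+FP+FN) + TN/(TN+FN+FP))`, boundary-F1 (MBF) with a match
tolerance of 0.75 % of the image diagonal, and segmentation speed
Ass `= N/T` in slices per second.

Because clinical CT cannot ship with a package, `ambbem` includes a
**phantom generator** that renders synthetic axial slices with
pixel-perfect ground truth — bright elliptical skull ring, Gaussian brain
parenchyma, optional hematoma, scalp, pillow, bone septa splitting the
brain into 2–3 regions, basis-cranii bone beds, and skull gaps of
controlled width — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from ambbem import (PhantomSpec, generate_phantom, extract_brain,
                    confusion, mpa, miou, mbf)

spec = PhantomSpec(image_size=512, n_skull_gaps=2, gap_width_px=4,
                   include_hematoma=True, include_pillow=True, seed=7)
sample = generate_phantom(spec)

result = extract_brain(sample.image)
print("slice class:", result.layer.name)
for state in result.closure_trace:
    print(f"  cycle {state.i}: q={state.q:.4f}  TV={state.TV:.4f} ({state.tv_source})")

c = confusion(result.final_mask, sample.truth_mask)
print(f"MPA  = {mpa(c):.4f}")
print(f"MIoU = {miou(c):.4f}")
print(f"MBF  = {mbf(result.final_mask, sample.truth_mask):.4f}")
```

prints

```
slice class: SINGLE_REGION
  cycle 0: q=0.0000  TV=0.8317 (regression)
  cycle 1: q=0.0000  TV=0.8317 (regression)
  cycle 2: q=0.0039  TV=0.8317 (regression)
  cycle 3: q=0.8213  TV=0.8317 (regression)
  cycle 4: q=0.8213  TV=0.8317 (regression)
  cycle 5: q=0.8213  TV=0.8317 (regression)
MPA  = 0.9991
MIoU = 0.9988
MBF  = 0.9881
```

Read the trace: the two 4-px skull gaps defeat the first fill (`q ≈ 0`),
the growing-radius closing seals them at cycle 3 (`q` jumps to 0.82), and
the 5-cycle cap then guards against the slightly-too-high regression
threshold — the returned mask is already complete.  The final mask agrees
with the ground truth to MIoU 0.9988.

## Command line

```bash
ambbem synth   --n 100 --out phantoms --seed 1       # phantom dataset + manifest
ambbem extract --input slices/ --output masks/ [--config cfg.yaml] [--debug]
ambbem train   --out clf.pkl --n 400 --seed 0        # improved ResNet50 on phantoms
ambbem eval    --pred masks/ --truth truth/ --report report.csv
```

`--debug` dumps the per-slice intermediates (skull `e1`, skull-free `e2`,
mask 1, mask 2) and the closure trace as JSON lines.  Every constant of
the method (the threshold offsets 15 and 20, the basis-cranii constant
0.2485, the 5-cycle cap, the 0.75 % boundary tolerance) is surfaced in
`PipelineConfig` / the YAML config.

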