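# Methods

This note records the models the package implements, the parameters that
matter, what the synthetic data does and does not emulate, and the choices
made where the design was genuinely open.

## Data model and coordinates

Volumes are 3D Hounsfield-unit arrays indexed `(z, y, x)` with axis-aligned
world metadata: `world = origin + index × spacing`, with `origin` and
`spacing` stored `(x, y, z)` in mm, matching the MetaImage and LUNA16
dialects. No direction-cosine matrix is modelled: curated challenge data is
axis-aligned, and supporting oriented scans would complicate every
downstream crop for no benefit here. Annotations are world-space centres
plus diameters; candidates travel as `seriesuid,coordX,coordY,coordZ,probability`
CSV rows.

## Phantom generator

The generator emulates the statistics the pipeline is sensitive to, not
anatomy:

- background: Gaussian noise (mean −850 HU, sd 30) plus a smooth
  low-frequency drift field (amplitude 40 HU), clamped below −550 HU so a
  nodule-free phantom stays clearly sub-tissue;
- nodules: spheres with a low-order angular perturbation of the radius
  (amplitude ≤ 12%) and a ~0.6 mm sigmoid edge, soft-tissue intensity drawn
  from [−50, 100] HU, diameters uniform in the 3–40 mm nodule range (capped
  so the blob fits the volume); centres rejection-sampled for separation;
- distractors: vessel-like tubes (radius 0.5–1.6 mm, −300 to −100 HU) and
  sub-detection-size blobs, deliberately *not* annotated;
- a `difficulty` knob in [0, 1] linearly interpolates nodule contrast
  toward the background mean; at 0, labelled patch classes are separable by
  a per-size mean-intensity threshold (asserted in tests).

Every generator is a pure function of `(seed, parameters)`. What the
phantom does **not** emulate: airway trees, lobar structure, pleural
attachment, scanner noise spectra, or the intensity overlap between nodules
and vasculature that makes real false-positive reduction hard. Passing the
training checks therefore demonstrates *capacity and correctness of the
pipeline plumbing*, not clinical performance.

## Preprocessing

Fixed order: clip to the [−1200, 600] HU lung window → per-volume Z-score →
coordinate transform → trilinear resample to 1 mm isotropic → cropping.
Z-score statistics are computed per volume over post-clip voxels, keeping
volumes independent (the common challenge practice). Resampling preserves
world positions; output shape is `round(shape × spacing / target)` per
axis. Stage-one inputs are three-channel slice triplets rescaled in-plane
to `out_size` (512 at full scale, 128 in the desk-scale presets; the
rescale is configuration, since phantoms are natively smaller than clinical
slices); edge slices are replicated at volume boundaries, and a nodule's
ground-truth box side is its diameter divided by the effective in-plane
spacing.

Augmentation, stage one: per nodule, extra triplets at neighbouring centre
slices — four (±1, ±2) above 20 mm, two (±1) for 10–20 mm, none at or below
10 mm. Stage two: from 70³/36³/20³ enclosing cubes, 25 seeded random crops
to 64³/32³/16³ — one fractional offset shared across the three scales, so
the crops stay co-registered (the ×25 total fixes only the product, not a
per-scale count; the shared-offset reading keeps the multiscale stack
consistent) — each expanded by all 8 axis-flip subsets, for exactly 200
samples per candidate. Out-of-bounds regions pad with the window minimum
(reads as air, the least informative tissue). Positives are double-sampled
into the training stream; negatives pass once.

## Anchor clustering

K-means++ seeding and Lloyd iterations under `D = 1 − IoU` of co-centred
`(w, h)` boxes. The centre update is the element-wise mean — the de-facto
anchor-clustering practice — but `1 − IoU` is not the distance the mean
minimises, so each update is accepted only if it does not increase the
objective; otherwise a medoid update is tried, and if that also fails the
iteration stops at the local optimum. This makes the recorded objective
trace non-increasing by construction. Ties in nearest-centre assignment
break toward the lowest centre index; an emptied cluster re-seeds from the
farthest box. Final centres are rounded to integer pixels and split three
per pyramid level by ascending area. The nine anchors fitted on the
full-scale cohort statistics ship as a named preset
(`anchors.PRINTED_ANCHOR_PRESET`); they are not reproducible from phantom
data and are not a test target.

## Detector

Backbone: bottleneck residual units (`h` identity, or a strided 1×1
projection when shapes change), stages at strides 4/8/16/32. Pyramid:
P4 = smooth₃ₓ₃(deconv×2(C5) + lat₁ₓ₁(C4)), with the top-down chain
continuing from the *pre-smoothing* sum (the chain order is ambiguous; the
presmooth reading is used and flagged here) and the 3×3 anti-aliasing
convolution applied per level. Upsampling is a learnable kernel-2 stride-2
transposed convolution. RPN: a shared 3×3 conv plus 1×1 objectness and
1×1 box-delta heads over every level; proposals are decoded with standard
centre/log-size offsets (clamped at ±4), NMS'd at 0.7 (top 300 kept) —
proposal counts and NMS thresholds are documented config defaults, not
claims. Anchor labelling follows the literal rule (IoU > 0.5 positive, else
negative, no ignore band) with a config flag restoring the conventional
0.3/0.7 bands; the training batch subsamples at most 256 anchors at 1:1.
ROI routing uses floor-then-clamp in the level rule (the worked example is
an exact power of two; floor sends borderline ROIs to the finer level),
ROI max-pooling uses a 7×7 grid (standard choice), and the head is
FC–FC–(cls, reg) with dropout 0.5. Loss = RPN BCE + RPN smooth-L1 + head
cross-entropy + head smooth-L1, unit weights.

Training: momentum SGD (momentum 0.9, weight decay 5e-4), initial LR 1e-3
with step decay, one image per step, ground-truth boxes appended to the
head's proposal pool so it always sees positives. Two architecture presets:
`full_scale` (ResNet-101-like depth, 256-channel pyramid, 512² inputs,
Gaussian(0, 0.01) init) is the printed layout and is verified by shape;
`tiny` (2 blocks/stage, 16–128 channels, 32-channel pyramid, 128² inputs,
~600 training steps) is what trains on one CPU core in about a minute.

## 3D false-positive filter

The full-width MSM-CNN follows the printed table exactly: per branch
C(3³,s1) → M → C → M with the pool kernels (1,1)/(2,1)/(2,2) for the
16³/32³/64³ inputs — kernel-1³ pools are implemented literally as identity
pools to preserve the printed structure — all exiting at 16³ × 64; merge by
element-wise addition; tail 128/256 channels down to 4³, then FC-1024,
FC-2, one softmax (the prose mentions two softmax layers, the table prints
one `Soft` row; the table wins). Dropout 0.5 sits after FC1 (placement
unstated; after the wide layer is where it regularises most). The `tiny`
spec divides the widths by 8 (4/8 branch, 16/32 tail, FC 64) and keeps
every shape transition.

Fusion: per cross-validation fold, each single-scale network trains on the
remaining folds; ε = misclassified / total on the held-out fold;
α = ½ ln((1−ε)/ε) (ε clamped to [1e-6, 1−1e-6]); final α are the fold
means. The fused score α₁p₁ + α₂p₂ + α₃p₃ is deliberately not renormalised
— classification compares fused per-class scores by argmax rather than
cutting at 0.5, which avoids inventing a threshold for an unnormalised sum.
Ensemble members train independently (whether they share tail weights is
unstated; independent training is the cleaner reading). The default is 5
folds; the desk-scale tests use 2–3 folds so each fold still holds both
classes at the small sample counts used.

## Evaluation

Hit criterion: candidate centre within the nodule radius (mm), the LUNA16
convention; a fixed-mm radius is available as config. Matching is greedy in
descending score, one credit per annotation; surplus hits on a credited
nodule count as false positives. The FROC sweeps every distinct score, and
each annotation is credited to its highest-scoring hit across the whole
sweep (the standard prefix approximation used by challenge tooling).
Sensitivities at the seven CPM rates come from linear interpolation between
bracketing operating points, 0 at rate 0, the final sensitivity beyond the
curve; CPM is their arithmetic mean. Report rounding is half-up at the
printed precision; diameter bins are left-closed ([3,5), [5,10), [10,20),
>20 mm), so a 5 mm nodule falls in the 5–10 bin. One published per-bin
percentage is internally inconsistent with its own counts under any fixed
rounding rule (193/198 → 97.5, printed 97.4); this module reports the
half-up value and does not replicate the discrepancy.

## The NumPy neural-network engine

No deep-learning framework is a dependency: `nodulenet.nn` is a compact
reverse-mode autodiff engine (tensors with backward closures, topological
sort) with the primitives the two networks need — N-D convolution via
strided sliding-window views and einsum (the input gradient of a strided
convolution is computed as the full correlation of the stride-dilated
output gradient with the flipped kernel), kernel-2 stride-2 transposed
convolution, non-overlapping max pooling, linear layers, dropout, ROI
max-pooling with recorded argmax indices, and the standard detection losses.
Every primitive's gradient is verified against central finite differences
in the test suite.

Numerical choices that mattered in practice, all asserted or exercised by
tests:

- **Initialisation.** The printed recipe (Gaussian, sd 0.01) is the default
  and the `full_scale` presets keep it. The narrow `tiny` networks starve under
  a fixed 0.01 sd (activations vanish through six-plus layers), so the tiny
  presets use He initialisation — except (a) each residual block's final
  1×1 expand convolution, which keeps the small fixed sd so blocks start
  near-identity (without normalisation layers, He there doubles the
  activation variance at every residual addition), and (b) all final
  prediction layers (RPN cls/reg, head cls/reg, classifier FC2), which
  start small so initial scores and box deltas sit near zero and the first
  optimisation steps are well-scaled.
- **Gradient clipping** at global norm 10 in both trainers, as insurance
  against the occasional large ROI-regression gradient.
- Sigmoid/exp inputs are clamped at ±60; box deltas decode with a ±4 clamp.
- Max pooling is restricted to kernel = stride (all the printed layouts
  need); sub-cell ROI bins fall back to the nearest single cell.

## Desk-scale study conditions

The tests train at sizes chosen once for a single CPU core: the detector
check uses 10 nodule-centred triplets from five phantoms (two nodules each,
default 3–40 mm diameters), 600 steps (~75 s), and asks for an operating
point with recall ≥ 0.9 at ≤ 8 FP/scan; the classifier check trains the
tiny MSM on 28 balanced multiscale crops for 10 epochs (~60 s), measures
accuracy on a held-out set, cross-validates fusion weights with 2 folds,
and compares the fused cohort CPM against the best single branch on a
12-positive/30-negative cohort. The full published training protocol
(hundreds of scans, tens of thousands of steps at batch 64) is reproduced
in the configuration defaults but is not exercised.

## Known limitations

- The phantom's difficulty-0 patch classes are separable by mean intensity,
  so classifier checks bound correctness, not discriminative power.
- The detector processes one image per optimisation step; there is no
  batching across images and no GPU path.
- FROC uses the prefix matching approximation (see above); exact per-
  threshold rematching would differ only when a nodule's lower-scored hit
  survives a threshold that removes its higher-scored hit.
- MetaImage support covers the uncompressed two-file dialect only (the one
  the pipeline writes); compressed or single-file variants are out of scope.
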