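# nodulenet

Two-stage pulmonary-nodule detection for thoracic CT, built desk-scale and
fully testable on synthetic phantoms.

Early lung cancer shows up in CT as small (3–40 mm) quasi-spherical nodules
that occupy a vanishing fraction of a scan and resemble vessels and other
soft tissue. Automated detection therefore runs in two stages: a
high-sensitivity **candidate detector** that proposes many boxes (most of
them false), followed by a **false-positive filter** that classifies each
candidate as nodule vs non-nodule in 3D. This package implements both
stages, the preprocessing that feeds them, anchor design by clustering, and
the field's standard evaluation (FROC curves and the CPM score), for users
who want a compact, inspectable, pure-NumPy reference implementation of the
whole pipeline — every layer, loss and gradient lives in this repository
and is verified against finite differences in the tests.

## The method

**Stage one** is a two-stage detector over three-channel axial "slice
triplets" (the nodule's centre slice and its two neighbours):

- a bottleneck-residual backbone, `y = f(h(x) + F(x, W))`, with a 1×1
  reduce / 3×3 / 1×1 expand structure per unit;
- a three-level feature pyramid: levels P2/P3/P4 at strides 4/8/16, built
  top-down by learnable ×2 deconvolution plus 1×1 lateral connections,
  with one uniform channel width per level. The coarsest backbone output
  only seeds the top-down path — nodules top out near 40 mm, so it gets no
  prediction level of its own;
- a region-proposal head sliding over every level, whose anchors are not
  hand-set but clustered from the ground-truth box sizes by K-means++ under
  the scale-aware distance **D(A, B) = 1 − IoU(A, B)** (an anchor whose
  sides double is equally "far" whether the box is small or large — the
  property Euclidean distance lacks). An anchor is labelled positive iff
  its IoU with a ground-truth box exceeds 0.5, otherwise negative;
- scale-based routing of each proposal to one pyramid level,
  **k = ⌊k₀ + log₂(√(wh)/40)⌋** with k₀ = 4 (an ROI at half the 40-px base
  scale routes to the finer P3), followed by ROI max-pooling to a fixed
  grid and a small fully connected classification/regression head.

**Stage two** is a 3D multiscale-merge CNN (MSM-CNN): three convolutional
branches read co-centred cubes of 16³/32³/64³ voxels around each candidate,
all exit at a common 16³ × 64 feature shape, are **merged by element-wise
addition** (`F_add = Σₖ Wₖ`), and share a convolutional tail ending in
FC-1024 / FC-2 / softmax. Each branch also forms a standalone classifier
(CNN1/CNN2/CNN3) with its own tail; the three are combined AdaBoost-style
with weights **α = ½ ln((1−ε)/ε)**, where ε is each model's held-out
misclassification rate from cross-validation, and the fused score is the
raw weighted sum α₁p₁ + α₂p₂ + α₃p₃.

**Evaluation** follows challenge convention: a candidate hits a nodule when
its centre lies within the nodule radius; the FROC curve sweeps the score
threshold; the **CPM** is the mean sensitivity at 1/8, 1/4, 1/2, 1, 2, 4
and 8 false positives per scan.

Because no scan data ships with the package, a seeded **phantom generator**
produces CT-like volumes (lung background near −850 HU, soft-tissue nodules
with perturbed-sphere shapes, vessel-like distractors) with matching
world-coordinate annotations, so every stage trains and evaluates
end-to-end on a desktop CPU.

## Worked example

`examples/` holds one short script per capability. Anchor clustering
(`examples/03_anchor_clustering.py`) on 36 phantom ground-truth boxes:

```
D((4,4),(8,8)) = 0.750 = D((40,40),(80,80)) = 0.750
36 ground-truth boxes -> 9 anchors (w x h, px):
  P2 (stride 4): [(4, 4), (6, 6), (8, 8)]
  P3 (stride 8): [(12, 12), (18, 18), (28, 28)]
  P4 (stride 16): [(31, 31), (33, 33), (38, 38)]
Lloyd objective per iteration: [3.37, 3.01]
```

Small anchors land on the fine stride-4 level, large ones on the coarse
level, and the clustering objective only ever decreases. FROC evaluation of
a hand-built cohort (`examples/06_froc_evaluation.py`, 3 nodules across 2
scans, 4 scored candidates):

```
FROC operating points (FP/scan, sensitivity):
  (0.00, 0.333)
  (0.00, 0.667)
  (0.50, 0.667)
  (1.00, 0.667)
CPM = 0.667
```

Two of three nodules are found before the first false positive appears, so
sensitivity is 2/3 at every CPM rate and the CPM is 0.667. The training
examples (`04`, `05`, `07`) overfit the tiny presets on phantoms and print
recall/FP-rate, classifier accuracy, and fusion weights.

A thin CLI mirrors the library: `nodulenet phantom make`, `anchors fit`,
`detector train/detect`, `fpfilter train/fuse`, `evaluate froc`,
`pipeline run`, `report`.

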