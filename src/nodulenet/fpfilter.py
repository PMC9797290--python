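"""Stage two: the 3D false-positive filter.

The multiscale-merge CNN (MSM-CNN) runs three 3D branches over co-centred
nodule cubes of sides 16/32/64 voxels, merges them by element-wise addition
at a common 16^3 x 64 feature shape, and shares a convolutional tail ending
in FC-1024 / FC-2 / softmax. Each branch also forms a standalone network
with the tail (CNN1 = 16^3 input, CNN2 = 32^3, CNN3 = 64^3); those three are
combined by AdaBoost-style weighting, alpha = 0.5 * ln((1 - eps) / eps) with
eps the held-out misclassification rate from cross-validation, and the fused
score is the raw weighted sum alpha1*p1 + alpha2*p2 + alpha3*p3 (no
renormalisation; classification compares the fused per-class scores).

Pooling rows with kernel 1^3 stride 1 are implemented literally as identity
pools to keep the printed layer structure intact.

The ``full_scale`` spec keeps the printed widths (32/64 branch channels, 128/256
tail, FC 1024); ``tiny`` scales widths down (4/8, 16/32, FC 64) for CPU
training while preserving every shape transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import ops
from .core import MultiscaleCrop
from .preprocess import HU_WINDOW

__all__ = [
    "MSMSpec",
    "TrainConfig",
    "FusionWeights",
    "MSMNet",
    "SingleScaleCNN",
    "build_msm",
    "merge_add",
    "fusion_weight",
    "fused_probability",
    "crossval_weights",
    "train_classifier",
    "predict_proba",
    "normalize_cube",
    "msm_shape_trace",
]

BRANCH_INPUT_SIDES = (16, 32, 64)  # Path1, Path2, Path3


@dataclass
class MSMSpec:
    """Widths of the three-branch + shared-tail architecture.

    Per-branch layers are (conv C1, pool M1, conv C2, pool M2) with 3^3
    kernels, stride 1 convs; pool kernels are fixed by the branch input side
    so every branch exits at 16^3 spatial:

    * Path1 (16^3): M1 = 1^3 (identity), M2 = 1^3
    * Path2 (32^3): M1 = 2^3/2,          M2 = 1^3
    * Path3 (64^3): M1 = 2^3/2,          M2 = 2^3/2
    """

    branch_c1: int = 32
    branch_c2: int = 64
    tail_c3: int = 128
    tail_c4: int = 256
    fc1: int = 1024
    dropout: float = 0.5
    init: str = "gaussian"  # weight init; the tiny preset uses "he"

    # pool kernels per branch, (M1, M2)
    POOLS = ((1, 1), (2, 1), (2, 2))

    @classmethod
    def full_scale(cls) -> "MSMSpec":
        return cls()

    @classmethod
    def tiny(cls) -> "MSMSpec":
        return cls(branch_c1=4, branch_c2=8, tail_c3=16, tail_c4=32, fc1=64, init="he")


@dataclass
class TrainConfig:
    """Classifier training recipe (printed defaults, desk-scale batch)."""

    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 64
    epochs: int = 10
    lr_step: int = 20000
    lr_gamma: float = 0.1
    seed: int = 0


@dataclass
class FusionWeights:
    """AdaBoost-style per-model weights and their provenance."""

    alphas: tuple[float, float, float]
    epsilons: tuple[float, float, float]
    fold_history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, e in zip(self.alphas, self.epsilons):
            if not 0.0 < e < 1.0:
                raise ValueError(f"epsilon {e} outside (0, 1)")
            if abs(a - fusion_weight(e)) > 1e-6:
                raise ValueError("alpha inconsistent with its epsilon")


class _Branch(nn.Module):
    def __init__(self, spec: MSMSpec, branch_index: int, rng: np.random.Generator) -> None:
        super().__init__()
        m1, m2 = MSMSpec.POOLS[branch_index]
        self.c1 = nn.Conv3d(1, spec.branch_c1, 3, rng=rng, init=spec.init)
        self.m1 = nn.MaxPool3d(m1)
        self.c2 = nn.Conv3d(spec.branch_c1, spec.branch_c2, 3, rng=rng, init=spec.init)
        self.m2 = nn.MaxPool3d(m2)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = ops.relu(self.m1(self.c1(x)))
        return ops.relu(self.m2(self.c2(h)))


class _Tail(nn.Module):
    def __init__(self, spec: MSMSpec, rng: np.random.Generator) -> None:
        super().__init__()
        self.c3 = nn.Conv3d(spec.branch_c2, spec.tail_c3, 3, rng=rng, init=spec.init)
        self.m3 = nn.MaxPool3d(2)
        self.c4 = nn.Conv3d(spec.tail_c3, spec.tail_c4, 3, rng=rng, init=spec.init)
        self.m4 = nn.MaxPool3d(2)
        self.fc1 = nn.Linear(spec.tail_c4 * 4**3, spec.fc1, rng=rng, init=spec.init)
        self.drop = nn.Dropout(spec.dropout, seed=int(rng.integers(2**31)))
        # the classification layer starts small so initial logits sit near 0
        self.fc2 = nn.Linear(spec.fc1, 2, rng=rng, init="gaussian")

    def forward(self, merged: nn.Tensor) -> nn.Tensor:
        h = ops.relu(self.m3(self.c3(merged)))
        h = ops.relu(self.m4(self.c4(h)))
        h = self.drop(ops.relu(self.fc1(ops.flatten(h))))
        return self.fc2(h)  # logits; softmax applied by the caller


def merge_add(*blocks: nn.Tensor) -> nn.Tensor:
    """Element-wise feature merge F_add = sum_k W_k (shapes must match)."""
    if not blocks:
        raise ValueError("nothing to merge")
    shapes = {tuple(b.shape) for b in blocks}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch in merge: {sorted(shapes)}")
    out = blocks[0]
    for b in blocks[1:]:
        out = ops.add(out, b)
    return out


class MSMNet(nn.Module):
    """The three-branch multiscale-merge classifier."""

    def __init__(self, spec: Optional[MSMSpec] = None, seed: int = 0) -> None:
        super().__init__()
        self.spec = spec or MSMSpec.full_scale()
        rng = np.random.default_rng(seed)
        self.branches = [_Branch(self.spec, i, rng) for i in range(3)]
        self.tail = _Tail(self.spec, rng)

    def forward(self, x16: nn.Tensor, x32: nn.Tensor, x64: nn.Tensor) -> nn.Tensor:
        """Logits for a batch of (N, 1, side^3) cubes at the three sides."""
        for x, side, name in ((x16, 16, "Path1"), (x32, 32, "Path2"), (x64, 64, "Path3")):
            if x.shape[2:] != (side,) * 3:
                raise ValueError(
                    f"{name} expects a {side}^3 cube, got spatial shape {x.shape[2:]}"
                )
        feats = [b(x) for b, x in zip(self.branches, (x16, x32, x64))]
        return self.tail(merge_add(*feats))


class SingleScaleCNN(nn.Module):
    """One branch + its own tail: CNN1 (16^3), CNN2 (32^3) or CNN3 (64^3)."""

    def __init__(self, scale_index: int, spec: Optional[MSMSpec] = None, seed: int = 0) -> None:
        super().__init__()
        if scale_index not in (0, 1, 2):
            raise ValueError("scale_index must be 0 (16^3), 1 (32^3) or 2 (64^3)")
        self.spec = spec or MSMSpec.full_scale()
        self.scale_index = scale_index
        rng = np.random.default_rng(seed)
        self.branch = _Branch(self.spec, scale_index, rng)
        self.tail = _Tail(self.spec, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        side = BRANCH_INPUT_SIDES[self.scale_index]
        if x.shape[2:] != (side,) * 3:
            raise ValueError(f"expected a {side}^3 cube, got {x.shape[2:]}")
        return self.tail(self.branch(x))


def build_msm(spec: Optional[MSMSpec] = None, seed: int = 0) -> MSMNet:
    """Construct the multiscale-merge network from a width spec."""
    return MSMNet(spec, seed)


def msm_shape_trace(spec: Optional[MSMSpec] = None) -> dict[str, list[tuple]]:
    """Symbolic layer-by-layer (spatial_side^3, channels) shape propagation.

    Walks the architecture arithmetic without allocating feature maps, so
    the full-width layout can be verified cheaply.
    """
    spec = spec or MSMSpec.full_scale()
    trace: dict[str, list[tuple]] = {}
    for i, side in enumerate(BRANCH_INPUT_SIDES):
        m1, m2 = MSMSpec.POOLS[i]
        s = side
        seq = [(s, 1)]
        seq.append((s, spec.branch_c1))        # C1, 3^3 stride 1, same padding
        s //= m1
        seq.append((s, spec.branch_c1))        # M1
        seq.append((s, spec.branch_c2))        # C2
        s //= m2
        seq.append((s, spec.branch_c2))        # M2
        trace[f"Path{i + 1}"] = seq
    s = 16
    tail = [(s, spec.branch_c2)]               # Merge
    tail.append((s, spec.tail_c3))             # C3
    s //= 2
    tail.append((s, spec.tail_c3))             # M3
    tail.append((s, spec.tail_c4))             # C4
    s //= 2
    tail.append((s, spec.tail_c4))             # M4
    trace["Tail"] = tail
    trace["FC"] = [(spec.fc1,), (2,), (2,)]    # FC1, FC2, softmax
    return trace


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fusion_weight(epsilon: float) -> float:
    """AdaBoost model weight alpha = 0.5 * ln((1 - eps) / eps).

    ``eps`` is the misclassification rate; values are clamped to
    [1e-6, 1 - 1e-6] before the log. Decreasing in eps, zero at eps = 0.5.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon {epsilon} outside [0, 1]")
    e = float(np.clip(epsilon, 1e-6, 1 - 1e-6))
    return 0.5 * float(np.log((1 - e) / e))


def fused_probability(p1, p2, p3, weights: FusionWeights | Sequence[float]):
    """Weighted-sum fusion p = a1*p1 + a2*p2 + a3*p3, exactly as defined.

    The sum is deliberately not renormalised; downstream classification
    compares fused per-class scores rather than cutting at 0.5.
    """
    alphas = weights.alphas if isinstance(weights, FusionWeights) else tuple(weights)
    p1, p2, p3 = (np.asarray(p) for p in (p1, p2, p3))
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)) or np.any((p3 < 0) | (p3 > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = alphas[0] * p1 + alphas[1] * p2 + alphas[2] * p3
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def normalize_cube(cube: np.ndarray) -> np.ndarray:
    """Window-affine intensity normalisation of a raw-HU cube onto [0, 1].

    Already-standardised inputs (|values| of order 1) pass through unchanged.
    """
    cube = np.asarray(cube, dtype=np.float32)
    if np.abs(cube).max() <= 50:
        return cube
    lo, hi = HU_WINDOW
    return (np.clip(cube, lo, hi) - lo) / (hi - lo)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _model_inputs(model: nn.Module, crops: Sequence[MultiscaleCrop], idx) -> tuple:
    """Stack the cube scale(s) a model consumes into (N, 1, s, s, s) tensors."""
    def stack(scale: int) -> nn.Tensor:
        # MultiscaleCrop stores (64, 32, 16); scale 0 -> 16^3 etc.
        cube_pos = {0: 2, 1: 1, 2: 0}[scale]
        arr = np.stack([normalize_cube(crops[i].cubes[cube_pos]) for i in idx])
        return nn.Tensor(arr[:, None].astype(np.float32))

    if isinstance(model, MSMNet):
        return stack(0), stack(1), stack(2)
    return (stack(model.scale_index),)


def train_classifier(
    model: nn.Module,
    dataset: Sequence[MultiscaleCrop],
    config: Optional[TrainConfig] = None,
) -> list[dict[str, float]]:
    """Train an MSM or single-scale classifier in place; returns epoch log.

    Momentum-SGD with the package's printed defaults and softmax
    cross-entropy; the log records per-epoch loss, accuracy, sensitivity and
    specificity on the training stream. Seed-reproducible.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = config or TrainConfig()
    labels = np.array([c.label for c in dataset])
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay, clip_norm=10.0)
    sched = nn.StepLR(opt, cfg.lr_step, cfg.lr_gamma)
    log: list[dict[str, float]] = []
    model.train()
    for epoch in range(cfg.epochs):
        losses, preds, trues = [], [], []
        for idx in _batches(len(dataset), cfg.batch_size, rng):
            logits = model(*_model_inputs(model, dataset, idx))
            loss = ops.softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            sched.step()
            losses.append(float(loss.data))
            preds.extend(logits.data.argmax(axis=1))
            trues.extend(labels[idx])
        preds, trues = np.array(preds), np.array(trues)
        tp = int(((preds == 1) & (trues == 1)).sum())
        tn = int(((preds == 0) & (trues == 0)).sum())
        pos, negs = int((trues == 1).sum()), int((trues == 0).sum())
        log.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "accuracy": (tp + tn) / len(trues),
                "sensitivity": tp / pos if pos else float("nan"),
                "specificity": tn / negs if negs else float("nan"),
            }
        )
    return log


def predict_proba(
    model: nn.Module, dataset: Sequence[MultiscaleCrop], batch_size: int = 16
) -> np.ndarray:
    """Softmax class probabilities, (N, 2)."""
    model.eval()
    out = []
    for i in range(0, len(dataset), batch_size):
        idx = range(i, min(i + batch_size, len(dataset)))
        logits = model(*_model_inputs(model, dataset, idx))
        out.append(ops.softmax(logits).data)
    model.train()
    return np.concatenate(out)


def crossval_weights(
    dataset: Sequence[MultiscaleCrop],
    n_folds: int = 5,
    seed: int = 0,
    spec: Optional[MSMSpec] = None,
    config: Optional[TrainConfig] = None,
) -> FusionWeights:
    """Cross-validated AdaBoost weights for the CNN1/CNN2/CNN3 ensemble.

    Per fold, each single-scale network is trained on the remaining folds
    and its misclassification rate eps is measured on the held-out fold;
    alpha = 0.5 * ln((1 - eps) / eps). The final alphas are the means over
    the folds of the (single) cross-validation round; fold provenance is
    kept on the result.
    """
    labels = np.array([c.label for c in dataset])
    if n_folds < 2 or n_folds > len(dataset):
        raise ValueError("n_folds must be in [2, n_samples]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    folds = np.array_split(order, n_folds)
    for f in folds:
        if len(np.unique(labels[f])) < 2:
            raise ValueError("every fold must contain both classes")
    cfg = config or TrainConfig()
    history: list[dict] = []
    alphas_per_fold = []
    for fi, held in enumerate(folds):
        train_idx = np.concatenate([f for fj, f in enumerate(folds) if fj != fi])
        train_set = [dataset[i] for i in train_idx]
        held_set = [dataset[i] for i in held]
        fold_alphas, fold_eps = [], []
        for scale in range(3):
            net = SingleScaleCNN(scale, spec, seed=seed + 100 * fi + scale)
            fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fi})
            train_classifier(net, train_set, fold_cfg)
            probs = predict_proba(net, held_set)
            preds = probs.argmax(axis=1)
            eps = float((preds != labels[held]).mean())
            fold_eps.append(eps)
            fold_alphas.append(fusion_weight(eps))
        alphas_per_fold.append(fold_alphas)
        history.append({"fold": fi, "epsilons": fold_eps, "alphas": fold_alphas})
    mean_alpha = tuple(float(a) for a in np.mean(alphas_per_fold, axis=0))
    # alpha is the averaged quantity; the stored eps is recovered through
    # the inverse link so the pair stays internally consistent
    implied_eps = tuple(1.0 / (1.0 + float(np.exp(2 * a))) for a in mean_alpha)
    return FusionWeights(alphas=mean_alpha, epsilons=implied_eps, fold_history=history)
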