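"""Stage one: the candidate-nodule detector.

A two-stage detector over three-channel slice triplets: a bottleneck-residual
backbone feeds a three-level feature pyramid (P2/P3/P4 at strides 4/8/16,
one uniform channel width; the coarsest backbone stage only seeds the
top-down path and has no prediction level of its own, since nodules top out
around 40 mm). A region-proposal head slides over every pyramid level with
clustered anchors; proposals are routed back to a single level by the
scale-based assignment rule k = k0 + log2(sqrt(w*h)/40), ROI-max-pooled to a
fixed grid and scored/refined by a small fully connected head.

Two presets exist: ``full`` mirrors the full-scale layout (ResNet-101-like
depth, 256-channel pyramid, 512^2 inputs) and is used for shape contracts;
``tiny`` (2 blocks per stage, 16-128 channels, 32-channel pyramid, 128^2
inputs) is trainable on a desktop CPU and is what the tests train.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import ops
from .anchors import AnchorSet, PRINTED_ANCHOR_PRESET
from .core import Detection, SliceTriplet

__all__ = [
    "DetectorConfig",
    "Bottleneck",
    "Backbone",
    "FeaturePyramid",
    "NoduleDetector",
    "roi_level",
    "label_anchors",
    "nms",
    "detect",
    "train_detector",
    "save_model",
    "load_model",
]

ROI_LEVEL_BASE = 40.0
ROI_LEVEL_K0 = 4
PYRAMID_LEVELS = (2, 3, 4)
LEVEL_STRIDES = {2: 4, 3: 8, 4: 16}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class DetectorConfig:
    """Architecture + training hyperparameters.

    Training defaults follow the printed recipe: momentum-SGD (momentum 0.9,
    weight decay 5e-4), Gaussian(0, 0.01) init, dropout 0.5 in the head FC
    layers, initial LR 1e-3 with step decay.
    """

    preset: str = "tiny"
    input_size: int = 128
    stem_channels: int = 16
    stage_channels: tuple[int, ...] = (32, 64, 96, 128)  # C2..C5
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    bottleneck_reduction: int = 4
    fpn_channels: int = 32
    roi_grid: int = 7
    head_fc: int = 256
    dropout: float = 0.5
    # anchor labelling: the literal rule (IoU > 0.5 positive, else negative)
    literal_anchor_rule: bool = True
    rpn_batch: int = 256
    rpn_pre_nms: int = 1000
    rpn_post_nms: int = 300
    rpn_nms_iou: float = 0.7
    final_nms_iou: float = 0.3
    score_thresh: float = 0.5
    roi_batch: int = 64
    # optimisation
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    lr_step: int = 20000
    lr_gamma: float = 0.1
    steps: int = 600
    seed: int = 0
    init: str = "he"  # weight init; the full-scale preset uses "gaussian"

    @classmethod
    def full_scale(cls) -> "DetectorConfig":
        """Full-scale layout (for shape contracts, not CPU training)."""
        return cls(
            preset="full",
            input_size=512,
            stem_channels=64,
            stage_channels=(256, 512, 1024, 2048),
            blocks_per_stage=(3, 4, 23, 3),
            fpn_channels=256,
            head_fc=1024,
            lr_step=20000,
            steps=40000,
            init="gaussian",
        )

    @classmethod
    def tiny(cls, **overrides) -> "DetectorConfig":
        return cls(**overrides)


# ---------------------------------------------------------------------------
# Network modules
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    """Residual unit y = f(h(x) + F(x)): 1x1 reduce, 3x3, 1x1 expand.

    ``h`` is the identity when shapes match, else a strided 1x1 projection.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        stride: int,
        reduction: int,
        rng: np.random.Generator,
        init: str = "he",
    ) -> None:
        super().__init__()
        mid = max(1, out_ch // reduction)
        self.reduce = nn.Conv2d(in_ch, mid, 1, rng=rng, init=init)
        self.conv = nn.Conv2d(mid, mid, 3, stride=stride, rng=rng, init=init)
        # the expand conv always uses the small fixed-std init so each block
        # starts near-identity; without normalisation layers, He init here
        # would double the activation variance at every residual addition
        self.expand = nn.Conv2d(mid, out_ch, 1, rng=rng, init="gaussian")
        self.project = (
            nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng, init=init)
            if (in_ch != out_ch or stride != 1)
            else None
        )

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        f = self.expand(ops.relu(self.conv(ops.relu(self.reduce(x)))))
        h = self.project(x) if self.project is not None else x
        return ops.relu(ops.add(h, f))


class Backbone(nn.Module):
    """Bottleneck-residual backbone emitting C2..C5 at strides 4/8/16/32."""

    def __init__(self, cfg: DetectorConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.stem = nn.Conv2d(3, cfg.stem_channels, 3, stride=2, rng=rng, init=cfg.init)
        self.pool = nn.MaxPool2d(2)
        self.stages = []
        in_ch = cfg.stem_channels
        for si, (ch, n_blocks) in enumerate(zip(cfg.stage_channels, cfg.blocks_per_stage)):
            blocks = []
            for bi in range(n_blocks):
                stride = 2 if (bi == 0 and si > 0) else 1
                blocks.append(
                    Bottleneck(in_ch, ch, stride, cfg.bottleneck_reduction, rng, cfg.init)
                )
                in_ch = ch
            self.stages.append(nn.Sequential(*blocks))

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, ...]:
        x = self.pool(ops.relu(self.stem(x)))
        outs = []
        for stage in self.stages:
            x = stage(x)
            outs.append(x)
        return tuple(outs)  # C2, C3, C4, C5


class FeaturePyramid(nn.Module):
    """Top-down pyramid builder: P2/P3/P4, each ``fpn_channels`` wide.

    P4 = smooth3x3( deconv_x2(C5) + lateral1x1(C4) ), and the top-down chain
    repeats from the pre-smoothing sum: the 3x3 anti-aliasing convolution is
    applied per level after the additions (presmooth reading of the chain).
    C5 itself gets no prediction level.
    """

    def __init__(self, cfg: DetectorConfig, rng: np.random.Generator) -> None:
        super().__init__()
        c2, c3, c4, c5 = cfg.stage_channels
        f = cfg.fpn_channels
        init = cfg.init
        self.up5 = nn.ConvTranspose2d(c5, f, rng=rng, init=init)
        self.up4 = nn.ConvTranspose2d(f, f, rng=rng, init=init)
        self.up3 = nn.ConvTranspose2d(f, f, rng=rng, init=init)
        self.lat4 = nn.Conv2d(c4, f, 1, rng=rng, init=init)
        self.lat3 = nn.Conv2d(c3, f, 1, rng=rng, init=init)
        self.lat2 = nn.Conv2d(c2, f, 1, rng=rng, init=init)
        self.smooth4 = nn.Conv2d(f, f, 3, rng=rng, init=init)
        self.smooth3 = nn.Conv2d(f, f, 3, rng=rng, init=init)
        self.smooth2 = nn.Conv2d(f, f, 3, rng=rng, init=init)

    def forward(self, c2, c3, c4, c5) -> dict[int, nn.Tensor]:
        m4 = ops.add(self.up5(c5), self.lat4(c4))
        m3 = ops.add(self.up4(m4), self.lat3(c3))
        m2 = ops.add(self.up3(m3), self.lat2(c2))
        return {4: self.smooth4(m4), 3: self.smooth3(m3), 2: self.smooth2(m2)}

    # spec-facing alias
    build_pyramid = forward


class RPNHead(nn.Module):
    """Shared sliding head: 3x3 conv then 1x1 objectness / 1x1 box deltas."""

    def __init__(
        self, channels: int, n_anchors: int, rng: np.random.Generator, init: str = "he"
    ) -> None:
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, rng=rng, init=init)
        # prediction layers start small so initial scores/deltas sit near 0
        self.cls = nn.Conv2d(channels, n_anchors, 1, rng=rng, init="gaussian")
        self.reg = nn.Conv2d(channels, 4 * n_anchors, 1, rng=rng, init="gaussian")

    def forward(self, feat: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = ops.relu(self.conv(feat))
        return self.cls(h), self.reg(h)


class RoIHead(nn.Module):
    """Pooled-ROI classifier/regressor: two FC layers with dropout."""

    def __init__(self, cfg: DetectorConfig, rng: np.random.Generator) -> None:
        super().__init__()
        in_f = cfg.fpn_channels * cfg.roi_grid**2
        self.fc1 = nn.Linear(in_f, cfg.head_fc, rng=rng, init=cfg.init)
        self.fc2 = nn.Linear(cfg.head_fc, cfg.head_fc, rng=rng, init=cfg.init)
        self.drop1 = nn.Dropout(cfg.dropout, seed=int(rng.integers(2**31)))
        self.drop2 = nn.Dropout(cfg.dropout, seed=int(rng.integers(2**31)))
        self.cls = nn.Linear(cfg.head_fc, 2, rng=rng, init="gaussian")
        self.reg = nn.Linear(cfg.head_fc, 4, rng=rng, init="gaussian")

    def forward(self, pooled: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = self.drop1(ops.relu(self.fc1(ops.flatten(pooled))))
        h = self.drop2(ops.relu(self.fc2(h)))
        return self.cls(h), self.reg(h)


class NoduleDetector(nn.Module):
    """The full two-stage model; anchors come from an :class:`AnchorSet`."""

    def __init__(self, cfg: DetectorConfig, anchor_set: Optional[AnchorSet] = None) -> None:
        super().__init__()
        self.cfg = cfg
        if anchor_set is None:
            boxes = list(PRINTED_ANCHOR_PRESET)
            split = [boxes[i : i + 3] for i in range(0, 9, 3)]
            anchor_set = AnchorSet(boxes=boxes, per_level={2: split[0], 3: split[1], 4: split[2]})
        self.anchor_set = anchor_set
        n_per_level = {lvl: len(v) for lvl, v in anchor_set.per_level.items()}
        if len(set(n_per_level.values())) != 1:
            raise ValueError("all pyramid levels must carry the same anchor count")
        self.n_anchors = next(iter(n_per_level.values()))
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg, rng)
        self.fpn = FeaturePyramid(cfg, rng)
        self.rpn = RPNHead(cfg.fpn_channels, self.n_anchors, rng, cfg.init)
        self.head = RoIHead(cfg, rng)

    # -- anchors ------------------------------------------------------------
    def level_anchors(self, level: int, fh: int, fw: int) -> np.ndarray:
        """All anchors of one level as (fh*fw*A, 4) xyxy pixel boxes."""
        stride = LEVEL_STRIDES[level]
        whs = np.array(self.anchor_set.per_level[level], dtype=float)
        cy = (np.arange(fh) + 0.5) * stride
        cx = (np.arange(fw) + 0.5) * stride
        cxg, cyg = np.meshgrid(cx, cy)  # (fh, fw)
        centers = np.stack([cxg, cyg], axis=-1)[:, :, None, :]  # fh,fw,1,2
        half = whs[None, None, :, :] / 2.0  # 1,1,A,2
        boxes = np.concatenate([centers - half, centers + half], axis=-1)
        return boxes.reshape(-1, 4)

    def forward_pyramid(self, image: np.ndarray) -> dict[int, nn.Tensor]:
        x = nn.Tensor(image[None].astype(np.float32))
        c2, c3, c4, c5 = self.backbone(x)
        return self.fpn(c2, c3, c4, c5)


# ---------------------------------------------------------------------------
# Box utilities
# ---------------------------------------------------------------------------

def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N, 4) vs (M, 4) xyxy boxes."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def encode_boxes(anchors: np.ndarray, gts: np.ndarray) -> np.ndarray:
    """Standard centre/log-size offsets of gts relative to anchors."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    gw = gts[:, 2] - gts[:, 0]
    gh = gts[:, 3] - gts[:, 1]
    gx = gts[:, 0] + gw / 2
    gy = gts[:, 1] + gh / 2
    return np.stack(
        [(gx - ax) / aw, (gy - ay) / ah, np.log(gw / aw), np.log(gh / ah)], axis=1
    )


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    d = np.clip(deltas, -4.0, 4.0)
    cx = ax + d[:, 0] * aw
    cy = ay + d[:, 1] * ah
    w = aw * np.exp(d[:, 2])
    h = ah * np.exp(d[:, 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def roi_level(
    w: float, h: float, k0: int = ROI_LEVEL_K0, base: float = ROI_LEVEL_BASE
) -> int:
    """Assign an ROI to a pyramid level: k = floor(k0 + log2(sqrt(wh)/base)).

    The floor routes borderline ROIs to the finer level; the result is
    clamped to the available levels {2, 3, 4}.
    """
    if w <= 0 or h <= 0:
        raise ValueError("ROI dimensions must be positive")
    k = math.floor(k0 + math.log2(math.sqrt(w * h) / base))
    return int(np.clip(k, PYRAMID_LEVELS[0], PYRAMID_LEVELS[-1]))


def label_anchors(
    anchors: np.ndarray,
    gt_boxes: np.ndarray,
    rng: np.random.Generator,
    batch: int = 256,
    pos_iou: float = 0.5,
    neg_iou: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Label anchors against ground truth and subsample a training batch.

    The default follows the literal rule: IoU > 0.5 with any ground-truth box
    is positive, everything else negative (no ignore band). Passing
    ``neg_iou`` (e.g. 0.3 with ``pos_iou=0.7``) restores the conventional
    ignore band. Returns (labels, regression targets, sampled positive
    indices, sampled negative indices); labels are 1/0/-1 (-1 = ignored).
    """
    n = len(anchors)
    labels = np.zeros(n, dtype=int)
    targets = np.zeros((n, 4))
    if len(gt_boxes):
        iou = box_iou(anchors, gt_boxes)
        best = iou.argmax(axis=1)
        best_iou = iou[np.arange(n), best]
        labels = (best_iou > pos_iou).astype(int)
        if neg_iou is not None:
            labels[(best_iou > neg_iou) & (best_iou <= pos_iou)] = -1
        pos = np.flatnonzero(labels == 1)
        if len(pos):
            targets[pos] = encode_boxes(anchors[pos], gt_boxes[best[pos]])
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    # subsample at a 1:1 positive:negative ratio, batch-size capped
    n_pos = min(len(pos_idx), batch // 2)
    if len(pos_idx) > n_pos:
        pos_idx = rng.choice(pos_idx, n_pos, replace=False)
    n_neg = min(len(neg_idx), n_pos if n_pos else batch // 2)
    if len(neg_idx) > n_neg:
        neg_idx = rng.choice(neg_idx, n_neg, replace=False)
    return labels, targets, pos_idx, neg_idx


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-descending."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        iou = box_iou(boxes[i][None], boxes[rest])[0]
        order = rest[iou <= iou_thresh]
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def _rpn_proposals(
    model: NoduleDetector, pyramid: dict[int, nn.Tensor]
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Decode RPN outputs into scored proposals (also returns raw tensors)."""
    cfg = model.cfg
    raw = {}
    all_boxes, all_scores = [], []
    for lvl in PYRAMID_LEVELS:
        cls, reg = model.rpn(pyramid[lvl])
        raw[lvl] = (cls, reg)
        _, a, fh, fw = cls.shape
        anchors = model.level_anchors(lvl, fh, fw)
        logits = np.clip(cls.data[0].transpose(1, 2, 0).reshape(-1), -60, 60)
        scores = 1.0 / (1.0 + np.exp(-logits))
        deltas = (
            reg.data[0]
            .reshape(a, 4, fh, fw)
            .transpose(2, 3, 0, 1)
            .reshape(-1, 4)
        )
        boxes = decode_boxes(anchors, deltas)
        np.clip(boxes[:, 0::2], 0, cfg.input_size, out=boxes[:, 0::2])
        np.clip(boxes[:, 1::2], 0, cfg.input_size, out=boxes[:, 1::2])
        valid = (boxes[:, 2] - boxes[:, 0] > 1) & (boxes[:, 3] - boxes[:, 1] > 1)
        all_boxes.append(boxes[valid])
        all_scores.append(scores[valid])
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    if len(scores) > cfg.rpn_pre_nms:
        top = np.argpartition(-scores, cfg.rpn_pre_nms)[: cfg.rpn_pre_nms]
        boxes, scores = boxes[top], scores[top]
    keep = nms(boxes, scores, cfg.rpn_nms_iou)[: cfg.rpn_post_nms]
    return boxes[keep], scores[keep], raw


def _pool_rois(
    model: NoduleDetector, pyramid: dict[int, nn.Tensor], rois: np.ndarray
) -> nn.Tensor:
    """Route each ROI to its pyramid level and max-pool a fixed grid."""
    pooled = []
    for roi in rois:
        w, h = roi[2] - roi[0], roi[3] - roi[1]
        lvl = roi_level(w, h)
        stride = LEVEL_STRIDES[lvl]
        feat = pyramid[lvl]
        fmap = ops.reshape(feat, feat.shape[1:])  # (C, H, W), batch of one
        pooled.append(ops.roi_pool(fmap, (roi / stride)[None], grid=model.cfg.roi_grid))
    blocks = [ops.reshape(p, p.shape[1:]) for p in pooled]
    return ops.stack0(blocks)  # (R, C, g, g)


def detect(
    triplets: Sequence[SliceTriplet],
    model: NoduleDetector,
    score_thresh: Optional[float] = None,
    nms_iou: Optional[float] = None,
) -> list[Detection]:
    """Run the trained detector on preprocessed slice triplets.

    Inputs must be standardised the way training inputs were; a raw-HU range
    triggers a refusal. Detections come back sorted by descending score.
    """
    cfg = model.cfg
    score_thresh = cfg.score_thresh if score_thresh is None else score_thresh
    nms_iou = cfg.final_nms_iou if nms_iou is None else nms_iou
    model.eval()
    out: list[Detection] = []
    for trip in triplets:
        if np.abs(trip.image).max() > 50:
            raise ValueError(
                "input does not look standardised (|values| >> 1); run preprocessing first"
            )
        pyramid = model.forward_pyramid(trip.image)
        props, _, _ = _rpn_proposals(model, pyramid)
        if not len(props):
            continue
        pooled = _pool_rois(model, pyramid, props)
        cls, reg = model.head(pooled)
        probs = ops.softmax(cls).data[:, 1]
        boxes = decode_boxes(props, reg.data)
        np.clip(boxes[:, 0::2], 0, cfg.input_size, out=boxes[:, 0::2])
        np.clip(boxes[:, 1::2], 0, cfg.input_size, out=boxes[:, 1::2])
        sel = (
            (probs >= score_thresh)
            & (boxes[:, 2] - boxes[:, 0] > 1)
            & (boxes[:, 3] - boxes[:, 1] > 1)
        )
        boxes, probs = boxes[sel], probs[sel]
        if not len(boxes):
            continue
        keep = nms(boxes, probs, nms_iou)
        for i in keep:
            out.append(
                Detection(
                    scan_id=trip.scan_id,
                    slice_index=trip.center_slice_index,
                    box=tuple(boxes[i]),
                    score=float(probs[i]),
                )
            )
    out.sort(key=lambda d: -d.score)
    model.train()
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _image_loss(
    model: NoduleDetector, trip: SliceTriplet, rng: np.random.Generator
) -> tuple[nn.Tensor, dict[str, float]]:
    cfg = model.cfg
    gt = np.array(trip.boxes, dtype=float).reshape(-1, 4)
    pyramid = model.forward_pyramid(trip.image)

    # --- RPN losses over all levels
    cls_logits, reg_preds, anchors_all = [], [], []
    for lvl in PYRAMID_LEVELS:
        cls, reg = model.rpn(pyramid[lvl])
        _, a, fh, fw = cls.shape
        anchors_all.append(model.level_anchors(lvl, fh, fw))
        # flatten to (fh*fw*A,) resp (fh*fw*A, 4) matching anchor order
        cls_logits.append(
            ops.reshape(_move_anchor_axis(cls, a, fh, fw, 1), (fh * fw * a, 1))
        )
        reg_preds.append(ops.reshape(_move_anchor_axis(reg, a, fh, fw, 4), (fh * fw * a, 4)))
    anchors = np.concatenate(anchors_all)
    cls_cat = ops.reshape(ops.concat_rows(cls_logits), (len(anchors),))
    reg_cat = ops.concat_rows(reg_preds)
    neg_iou = None if cfg.literal_anchor_rule else 0.3
    pos_iou = 0.5 if cfg.literal_anchor_rule else 0.7
    _, targets, pos_idx, neg_idx = label_anchors(
        anchors, gt, rng, batch=cfg.rpn_batch, pos_iou=pos_iou, neg_iou=neg_iou
    )
    sample = np.concatenate([pos_idx, neg_idx]).astype(np.intp)
    sample_labels = np.concatenate([np.ones(len(pos_idx)), np.zeros(len(neg_idx))])
    rpn_cls_loss = ops.bce_with_logits(ops.take_rows(cls_cat, sample), sample_labels)
    if len(pos_idx):
        rpn_reg_loss = ops.smooth_l1(ops.take_rows(reg_cat, pos_idx), targets[pos_idx])
    else:
        rpn_reg_loss = nn.Tensor(np.asarray(0.0))

    # --- ROI head losses on sampled proposals (ground truth added so the
    # head always sees positives, standard two-stage practice)
    props, _, _ = _rpn_proposals(model, pyramid)
    props = np.concatenate([props, gt]) if len(gt) else props
    if len(props):
        iou = box_iou(props, gt) if len(gt) else np.zeros((len(props), 1))
        best = iou.argmax(axis=1) if len(gt) else np.zeros(len(props), dtype=int)
        best_iou = iou.max(axis=1) if len(gt) else np.zeros(len(props))
        roi_labels = (best_iou > 0.5).astype(int)
        pos = np.flatnonzero(roi_labels == 1)
        neg = np.flatnonzero(roi_labels == 0)
        n_pos = min(len(pos), cfg.roi_batch // 2)
        if len(pos) > n_pos:
            pos = rng.choice(pos, n_pos, replace=False)
        n_neg = min(len(neg), cfg.roi_batch - n_pos)
        if len(neg) > n_neg:
            neg = rng.choice(neg, n_neg, replace=False)
        sel = np.concatenate([pos, neg]).astype(int)
        if len(sel):
            pooled = _pool_rois(model, pyramid, props[sel])
            cls, reg = model.head(pooled)
            head_labels = roi_labels[sel]
            head_cls_loss = ops.softmax_cross_entropy(cls, head_labels)
            if len(pos) and len(gt):
                reg_targets = encode_boxes(props[pos], gt[best[pos]])
                head_reg_loss = ops.smooth_l1(
                    ops.take_rows(reg, np.arange(len(pos))), reg_targets
                )
            else:
                head_reg_loss = nn.Tensor(np.asarray(0.0))
        else:
            head_cls_loss = nn.Tensor(np.asarray(0.0))
            head_reg_loss = nn.Tensor(np.asarray(0.0))
    else:
        head_cls_loss = nn.Tensor(np.asarray(0.0))
        head_reg_loss = nn.Tensor(np.asarray(0.0))

    total = ops.add(
        ops.add(rpn_cls_loss, rpn_reg_loss), ops.add(head_cls_loss, head_reg_loss)
    )
    log = {
        "rpn_cls": float(rpn_cls_loss.data),
        "rpn_reg": float(rpn_reg_loss.data),
        "head_cls": float(head_cls_loss.data),
        "head_reg": float(head_reg_loss.data),
        "total": float(total.data),
    }
    return total, log


def _move_anchor_axis(t: nn.Tensor, a: int, fh: int, fw: int, per: int) -> nn.Tensor:
    """(1, A*per, fh, fw) -> (fh, fw, A, per) flattened-compatible layout."""
    return ops.transpose(ops.reshape(t, (a, per, fh, fw)), (2, 3, 0, 1))


def train_detector(
    triplets: Sequence[SliceTriplet],
    config: Optional[DetectorConfig] = None,
    anchor_set: Optional[AnchorSet] = None,
    model: Optional[NoduleDetector] = None,
) -> tuple[NoduleDetector, list[dict[str, float]]]:
    """Train the detector on slice triplets; returns (model, per-step log).

    One gradient step per image, cycling through the dataset; all randomness
    (init, sampling, dropout) derives from ``config.seed``.
    """
    if not triplets:
        raise ValueError("empty training dataset")
    cfg = config or DetectorConfig()
    if model is None:
        model = NoduleDetector(cfg, anchor_set)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.SGD(
        model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
        weight_decay=cfg.weight_decay, clip_norm=10.0,
    )
    sched = nn.StepLR(opt, cfg.lr_step, cfg.lr_gamma)
    log = []
    model.train()
    for step in range(cfg.steps):
        trip = triplets[step % len(triplets)]
        loss, entry = _image_loss(model, trip, rng)
        opt.zero_grad()
        loss.backward()
        opt.step()
        sched.step()
        entry["step"] = step
        log.append(entry)
    return model, log


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: NoduleDetector, path: str | Path) -> None:
    """Serialise weights + config + anchors into one .npz checkpoint."""
    path = Path(path)
    meta = {
        "config": asdict(model.cfg),
        "anchors": {
            "boxes": model.anchor_set.boxes,
            "per_level": {str(k): v for k, v in model.anchor_set.per_level.items()},
        },
    }
    arrays = {f"p{i}": p for i, p in enumerate(model.state_dict())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> NoduleDetector:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg_d = meta["config"]
    for key in ("stage_channels", "blocks_per_stage"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = DetectorConfig(**cfg_d)
    anchor_set = AnchorSet(
        boxes=[tuple(b) for b in meta["anchors"]["boxes"]],
        per_level={
            int(k): [tuple(b) for b in v] for k, v in meta["anchors"]["per_level"].items()
        },
    )
    model = NoduleDetector(cfg, anchor_set)
    n = len(model.parameters())
    model.load_state_dict([data[f"p{i}"] for i in range(n)])
    return model
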