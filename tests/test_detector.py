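"""Detector contracts: residual blocks, pyramid shapes, ROI routing and
pooling, anchor labelling, NMS, and training smoke behaviour."""

import numpy as np
import pytest

import nodulenet.nn as nn
from nodulenet import anchors, detector as det, phantom, preprocess
from nodulenet.nn import ops


rng = np.random.default_rng(0)


@pytest.fixture(scope="module")
def tiny_model():
    return det.NoduleDetector(det.DetectorConfig(seed=0))


@pytest.fixture(scope="module")
def training_setup():
    """Ten nodule-centred slice triplets from five phantoms, with anchors."""
    trips, all_ann = [], []
    vols = {}
    for i in range(5):
        vol, ann = phantom.generate_volume(seed=100 + i, n_nodules=2, n_distractors=2)
        pp = preprocess.preprocess_volume(vol)
        vols[pp.scan_id] = pp
        trips.extend(preprocess.make_slice_triplets(pp, ann, out_size=128))
        all_ann.extend(ann)
    aset = anchors.cluster_anchors(anchors.boxes_from_annotations(all_ann), k=9, seed=0)
    return trips, all_ann, vols, aset


# ---------------------------------------------------------------------------
# Residual blocks
# ---------------------------------------------------------------------------

def test_residual_identity_when_f_is_zero():
    block = det.Bottleneck(8, 8, stride=1, reduction=4, rng=np.random.default_rng(0))
    for p in [block.expand.weight, block.expand.bias]:
        p.data = np.zeros_like(p.data)
    x = nn.Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
    out = block(x)
    assert np.allclose(out.data, np.maximum(x.data, 0), atol=1e-6)


def test_stride_two_block_halves_spatial_dims():
    block = det.Bottleneck(8, 16, stride=2, reduction=4, rng=np.random.default_rng(0))
    x = nn.Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
    assert block(x).shape == (1, 16, 4, 4)


def test_bottleneck_has_fewer_parameters_than_plain_double_conv():
    c = 64
    mid = c // 4
    bottleneck = c * mid + 9 * mid * mid + mid * c  # 1x1 + 3x3 + 1x1
    plain = 2 * 9 * c * c  # two 3x3 convs at equal width
    assert bottleneck < plain


# ---------------------------------------------------------------------------
# Feature pyramid
# ---------------------------------------------------------------------------

def test_pyramid_shapes_follow_strides(tiny_model):
    x = rng.normal(size=(3, 128, 128)).astype(np.float32)
    pyr = tiny_model.forward_pyramid(x)
    for lvl, stride in det.LEVEL_STRIDES.items():
        assert pyr[lvl].shape[2:] == (128 // stride, 128 // stride)


def test_full_scale_pyramid_is_256_channels_everywhere():
    cfg = det.DetectorConfig.full_scale()
    assert cfg.fpn_channels == 256
    rng_ = np.random.default_rng(0)
    fpn = det.FeaturePyramid(cfg, rng_)
    # channel widths are fixed by the lateral/smooth weight shapes
    for smooth in (fpn.smooth2, fpn.smooth3, fpn.smooth4):
        assert smooth.weight.data.shape[0] == 256
    for lat in (fpn.lat2, fpn.lat3, fpn.lat4):
        assert lat.weight.data.shape[0] == 256


def test_pyramid_is_zero_for_zero_input_when_biases_zero():
    cfg = det.DetectorConfig(seed=0)
    fpn = det.FeaturePyramid(cfg, np.random.default_rng(0))
    for m in fpn.modules():
        if hasattr(m, "bias") and m.bias is not None:
            m.bias.data = np.zeros_like(m.bias.data)
    c = [
        nn.Tensor(np.zeros((1, ch, 128 // s, 128 // s), dtype=np.float32))
        for ch, s in zip(cfg.stage_channels, (4, 8, 16, 32))
    ]
    pyr = fpn(*c)
    for t in pyr.values():
        assert np.allclose(t.data, 0.0)


# ---------------------------------------------------------------------------
# ROI level routing + pooling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "w,h,expected", [(40, 40, 4), (20, 20, 3), (200, 200, 4), (10, 10, 2), (1, 1, 2)]
)
def test_roi_level_examples(w, h, expected):
    assert det.roi_level(w, h) == expected


def test_roi_level_is_exhaustive_and_exclusive():
    for w in np.geomspace(1, 500, 40):
        for h in np.geomspace(1, 500, 7):
            assert det.roi_level(w, h) in (2, 3, 4)


def test_roi_pool_constant_map_and_identity_grid():
    feat = nn.Tensor(np.full((2, 8, 8), 3.5, dtype=np.float32))
    out = ops.roi_pool(feat, np.array([[1.0, 1.0, 6.0, 6.0]]), grid=3)
    assert np.allclose(out.data, 3.5)
    vals = np.arange(16, dtype=np.float32).reshape(1, 4, 4)
    out = ops.roi_pool(nn.Tensor(vals), np.array([[0.0, 0.0, 4.0, 4.0]]), grid=4)
    assert np.array_equal(out.data[0, 0], vals[0])  # g x g roi -> identity


def test_empty_roi_rejected():
    feat = nn.Tensor(np.zeros((1, 8, 8), dtype=np.float32))
    with pytest.raises(ValueError):
        ops.roi_pool(feat, np.array([[4.0, 4.0, 4.0, 5.0]]), grid=2)


# ---------------------------------------------------------------------------
# Anchor labelling + NMS
# ---------------------------------------------------------------------------

def test_label_anchors_literal_rule():
    anchors_xyxy = np.array([[0, 0, 10, 10], [50, 50, 60, 60], [0, 0, 4, 4]], dtype=float)
    gt = np.array([[0, 0, 10, 10]], dtype=float)
    labels, targets, pos, neg = det.label_anchors(
        anchors_xyxy, gt, np.random.default_rng(0)
    )
    assert labels[0] == 1  # identical box, IoU 1
    assert labels[1] == 0  # disjoint
    assert labels[2] == 0  # IoU 0.16 <= 0.5
    assert np.allclose(targets[0], 0.0)  # perfect match, zero offsets


def test_label_anchors_no_ground_truth_all_negative():
    anchors_xyxy = np.array([[0, 0, 10, 10], [5, 5, 15, 15]], dtype=float)
    labels, _, pos, neg = det.label_anchors(
        anchors_xyxy, np.zeros((0, 4)), np.random.default_rng(0)
    )
    assert np.all(labels == 0) and len(pos) == 0


def test_nms_merges_identical_boxes_and_is_idempotent():
    boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10], [40, 40, 50, 50]], dtype=float)
    scores = np.array([0.9, 0.8, 0.7])
    keep = det.nms(boxes, scores, 0.5)
    assert len(keep) == 2 and keep[0] == 0
    keep2 = det.nms(boxes[keep], scores[keep], 0.5)
    assert np.array_equal(boxes[keep][keep2], boxes[keep])


# ---------------------------------------------------------------------------
# Training + inference smoke
# ---------------------------------------------------------------------------

def test_train_rejects_empty_dataset():
    with pytest.raises(ValueError):
        det.train_detector([], det.DetectorConfig(steps=1))


def test_one_step_changes_parameters_and_seeded_init_is_reproducible(training_setup):
    trips, _, _, aset = training_setup
    cfg = det.DetectorConfig(steps=1, seed=0)
    m1, log1 = det.train_detector(trips[:2], cfg, aset)
    m2, log2 = det.train_detector(trips[:2], cfg, aset)
    assert log1[0]["total"] == log2[0]["total"]  # identical step-0 loss
    fresh = det.NoduleDetector(cfg, aset)
    changed = any(
        not np.array_equal(a, b) for a, b in zip(m1.state_dict(), fresh.state_dict())
    )
    assert changed


def test_loss_halves_during_short_overfit(training_setup):
    trips, _, _, aset = training_setup
    cfg = det.DetectorConfig(steps=120, seed=0)
    _, log = det.train_detector(trips[:4], cfg, aset)
    early = np.mean([e["total"] for e in log[:4]])
    late = np.mean([e["total"] for e in log[-4:]])
    assert late <= 0.5 * early


def test_detect_contracts(training_setup, tmp_path):
    trips, _, _, aset = training_setup
    cfg = det.DetectorConfig(steps=60, seed=0)
    model, _ = det.train_detector(trips[:4], cfg, aset)
    assert det.detect(trips[:2], model, score_thresh=1.0) == []
    dets = det.detect(trips[:2], model, score_thresh=0.0)
    scores = [d.score for d in dets]
    assert scores == sorted(scores, reverse=True)
    raw = trips[0]
    bad = type(raw)(image=raw.image * 1000, scan_id="x", center_slice_index=0, boxes=[])
    with pytest.raises(ValueError, match="standardised"):
        det.detect([bad], model)
    # checkpoint round trip preserves weights and anchors
    det.save_model(model, tmp_path / "m.npz")
    back = det.load_model(tmp_path / "m.npz")
    assert all(np.array_equal(a, b) for a, b in zip(model.state_dict(), back.state_dict()))
    assert back.anchor_set.boxes == model.anchor_set.boxes
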