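"""False-positive filter contracts: printed layer shapes, feature merge,
AdaBoost fusion arithmetic, and classifier training behaviour."""

import numpy as np
import pytest

import nodulenet.nn as nn
from nodulenet import fpfilter, phantom
from nodulenet.nn import ops


TINY = fpfilter.MSMSpec.tiny()


def test_shape_trace_matches_printed_structure():
    tr = fpfilter.msm_shape_trace(fpfilter.MSMSpec.full_scale())
    assert tr["Path1"] == [(16, 1), (16, 32), (16, 32), (16, 64), (16, 64)]
    assert tr["Path2"] == [(32, 1), (32, 32), (16, 32), (16, 64), (16, 64)]
    assert tr["Path3"] == [(64, 1), (64, 32), (32, 32), (32, 64), (16, 64)]
    assert tr["Tail"] == [(16, 64), (16, 128), (8, 128), (8, 256), (4, 256)]
    assert tr["FC"] == [(1024,), (2,), (2,)]


def test_tiny_forward_matches_trace_and_softmax_sums_to_one():
    net = fpfilter.build_msm(TINY, seed=0)
    x16 = nn.Tensor(np.random.default_rng(0).random((2, 1, 16, 16, 16), dtype=np.float32))
    x32 = nn.Tensor(np.random.default_rng(1).random((2, 1, 32, 32, 32), dtype=np.float32))
    x64 = nn.Tensor(np.random.default_rng(2).random((2, 1, 64, 64, 64), dtype=np.float32))
    feats = [b(x) for b, x in zip(net.branches, (x16, x32, x64))]
    for f in feats:
        assert f.shape == (2, TINY.branch_c2, 16, 16, 16)  # merge shape
    logits = net(x16, x32, x64)
    assert logits.shape == (2, 2)
    assert np.allclose(ops.softmax(logits).data.sum(axis=1), 1.0)


def test_wrong_input_side_names_the_branch():
    net = fpfilter.build_msm(TINY, seed=0)
    x = nn.Tensor(np.zeros((1, 1, 8, 8, 8), dtype=np.float32))
    good32 = nn.Tensor(np.zeros((1, 1, 32, 32, 32), dtype=np.float32))
    good64 = nn.Tensor(np.zeros((1, 1, 64, 64, 64), dtype=np.float32))
    with pytest.raises(ValueError, match="Path1"):
        net(x, good32, good64)


def test_zero_weight_network_outputs_half_half():
    net = fpfilter.build_msm(TINY, seed=0)
    for p in net.parameters():
        p.data = np.zeros_like(p.data)
    net.eval()
    logits = net(
        nn.Tensor(np.ones((1, 1, 16, 16, 16), dtype=np.float32)),
        nn.Tensor(np.ones((1, 1, 32, 32, 32), dtype=np.float32)),
        nn.Tensor(np.ones((1, 1, 64, 64, 64), dtype=np.float32)),
    )
    assert np.allclose(ops.softmax(logits).data, 0.5)


def test_merge_add_is_elementwise_sum_and_commutative():
    blocks = [nn.Tensor(np.random.default_rng(i).normal(size=(1, 4, 2, 2, 2))) for i in range(3)]
    merged = fpfilter.merge_add(*blocks)
    assert np.allclose(merged.data, sum(b.data for b in blocks))
    permuted = fpfilter.merge_add(blocks[2], blocks[0], blocks[1])
    assert np.allclose(permuted.data, merged.data)
    v = nn.Tensor(np.full((2, 2), 1.5))
    assert np.allclose(fpfilter.merge_add(v, v, v).data, 4.5)
    with pytest.raises(ValueError, match="mismatch"):
        fpfilter.merge_add(blocks[0], nn.Tensor(np.zeros((1, 4, 2, 2, 3))))


def test_single_scale_cnn_shares_tail_structure_at_the_merge():
    """With identical weights, the MSM run with the other branches' inputs
    zeroed produces the logits of tail(branch_i(x) + zero-branch outputs) —
    the merge is linear in its branch features."""
    msm = fpfilter.build_msm(TINY, seed=3)
    msm.eval()
    x32 = nn.Tensor(np.random.default_rng(5).random((1, 1, 32, 32, 32), dtype=np.float32))
    z16 = nn.Tensor(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
    z64 = nn.Tensor(np.zeros((1, 1, 64, 64, 64), dtype=np.float32))
    via_net = msm(z16, x32, z64)
    feats = [
        msm.branches[0](z16),
        msm.branches[1](x32),
        msm.branches[2](z64),
    ]
    via_manual = msm.tail(fpfilter.merge_add(*feats))
    assert np.allclose(via_net.data, via_manual.data, atol=1e-5)


# ---------------------------------------------------------------------------
# Fusion arithmetic
# ---------------------------------------------------------------------------

def test_fusion_weight_examples_and_properties():
    assert fpfilter.fusion_weight(0.5) == pytest.approx(0.0)
    assert fpfilter.fusion_weight(0.1) == pytest.approx(0.5 * np.log(9), abs=1e-9)
    eps = np.linspace(0.01, 0.99, 25)
    alphas = [fpfilter.fusion_weight(e) for e in eps]
    assert all(b < a for a, b in zip(alphas, alphas[1:]))  # strictly decreasing
    for e in (0.05, 0.3, 0.45):
        assert fpfilter.fusion_weight(e) == pytest.approx(-fpfilter.fusion_weight(1 - e))
    with pytest.raises(ValueError):
        fpfilter.fusion_weight(1.5)


def test_fused_probability_is_the_raw_weighted_sum():
    w = (2.0, 0.5, 1.0)
    assert fpfilter.fused_probability(0.5, 0.5, 0.5, w) == pytest.approx(1.75)
    assert fpfilter.fused_probability(0.9, 0.0, 0.0, (1.2, 0.0, 0.0)) == pytest.approx(1.08)
    p = np.array([0.2, 0.8])
    out = fpfilter.fused_probability(p, p, p, (1.0, 1.0, 1.0))
    assert np.allclose(out, 3 * p)  # equal alphas preserve the ranking
    with pytest.raises(ValueError):
        fpfilter.fused_probability(1.5, 0.0, 0.0, w)


def test_fused_scores_preserve_majority_ranking_with_equal_alphas():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p1, p2, p3 = rng.uniform(size=(3, 5))
        fused = fpfilter.fused_probability(p1, p2, p3, (1.0, 1.0, 1.0))
        assert np.array_equal(np.argsort(fused), np.argsort(p1 + p2 + p3))


def test_fusion_weights_validation():
    with pytest.raises(ValueError):
        fpfilter.FusionWeights(alphas=(0.0, 0.0, 0.0), epsilons=(0.5, 0.5, 1.5))
    with pytest.raises(ValueError):
        fpfilter.FusionWeights(alphas=(1.0, 0.0, 0.0), epsilons=(0.5, 0.5, 0.5))
    w = fpfilter.FusionWeights(
        alphas=tuple(fpfilter.fusion_weight(e) for e in (0.1, 0.2, 0.5)),
        epsilons=(0.1, 0.2, 0.5),
    )
    assert w.alphas[0] > w.alphas[1] > w.alphas[2]  # lower eps, higher weight


# ---------------------------------------------------------------------------
# Training behaviour
# ---------------------------------------------------------------------------

def test_train_classifier_rejects_empty_dataset():
    with pytest.raises(ValueError):
        fpfilter.train_classifier(fpfilter.build_msm(TINY), [], fpfilter.TrainConfig())


def test_crossval_rejects_single_class_fold():
    data = phantom.generate_multiscale_dataset(0, 0, 6)  # negatives only
    with pytest.raises(ValueError, match="both classes"):
        fpfilter.crossval_weights(data, n_folds=2, seed=0, spec=TINY)


def test_training_is_seed_reproducible_and_loss_decreases():
    data = phantom.generate_multiscale_dataset(2, 4, 4)
    cfg = fpfilter.TrainConfig(epochs=3, batch_size=4, seed=1)
    net_a = fpfilter.SingleScaleCNN(0, TINY, seed=5)
    log_a = fpfilter.train_classifier(net_a, data, cfg)
    net_b = fpfilter.SingleScaleCNN(0, TINY, seed=5)
    log_b = fpfilter.train_classifier(net_b, data, cfg)
    assert log_a[0] == log_b[0]  # identical first-epoch metrics
    assert log_a[-1]["loss"] < log_a[0]["loss"]


def test_normalize_cube_windows_raw_hu_and_passes_standardised():
    raw = np.array([-2000.0, -1200.0, 600.0, 0.0])
    out = fpfilter.normalize_cube(raw)
    assert out.min() >= 0 and out.max() <= 1
    assert out[0] == out[1] == 0.0  # below-window values clamp to 0
    std = np.array([-1.0, 0.0, 2.0], dtype=np.float32)
    assert np.array_equal(fpfilter.normalize_cube(std), std)
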