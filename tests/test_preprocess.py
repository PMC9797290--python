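"""Preprocessing contracts: windowing, standardisation, geometry,
slice triplets and both augmentation schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulenet import phantom, preprocess
from nodulenet.core import CTVolume, NoduleAnnotation


def _vol(voxels, origin=(0, 0, 0), spacing=(1, 1, 1)):
    return CTVolume(voxels=np.asarray(voxels), origin=origin, spacing=spacing, scan_id="t")


# ---------------------------------------------------------------------------
# Intensity
# ---------------------------------------------------------------------------

def test_clip_hu_clamps_and_preserves():
    x = np.array([-2000.0, 1000.0, -500.0])
    assert np.array_equal(preprocess.clip_hu(x), [-1200.0, 600.0, -500.0])


def test_zscore_closed_form_and_idempotence():
    x = np.array([0.0, 2.0, 0.0, 2.0])
    z = preprocess.zscore(x)
    assert np.allclose(z, [-1, 1, -1, 1])  # mean 1, sd 1
    assert np.allclose(preprocess.zscore(z), z, atol=1e-6)


def test_zscore_rejects_constant_input():
    with pytest.raises(ValueError):
        preprocess.zscore(np.full((4, 4, 4), 7.0))


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def test_world_to_voxel_worked_example():
    vol = _vol(np.zeros((4, 4, 4)), origin=(-200.0, -195.0, -378.0), spacing=(0.7, 0.7, 2.5))
    assert np.allclose(
        preprocess.world_to_voxel((-199.3, -195.0, -375.5), vol), (1.0, 0.0, 1.0)
    )
    assert np.allclose(preprocess.world_to_voxel(vol.origin, vol), (0, 0, 0))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    p=st.tuples(*[st.floats(-300, 300) for _ in range(3)]),
    spacing=st.tuples(*[st.floats(0.3, 3.0) for _ in range(3)]),
)
def test_coordinate_transforms_are_inverse(p, spacing):
    vol = _vol(np.zeros((2, 2, 2)), origin=(-100, -50, -200), spacing=spacing)
    back = preprocess.voxel_to_world(preprocess.world_to_voxel(p, vol), vol)
    assert np.allclose(back, p, atol=1e-9 * max(map(abs, p), default=1) + 1e-9)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def test_resample_is_noop_at_target_spacing():
    vol = _vol(np.random.default_rng(0).normal(size=(8, 8, 8)))
    out = preprocess.resample_isotropic(vol)
    assert np.array_equal(out.voxels, vol.voxels)


def test_resample_shape_arithmetic():
    vol = _vol(np.zeros((64, 64, 64), dtype=np.float32), spacing=(0.7, 0.7, 2.5))
    out = preprocess.resample_isotropic(vol)
    assert out.shape == (160, round(64 * 0.7), round(64 * 0.7))  # 64 * 2.5 / 1 = 160
    assert out.spacing == (1.0, 1.0, 1.0)


def test_resample_preserves_annotation_world_position():
    vol, ann = phantom.generate_volume(
        seed=4, shape=(40, 64, 64), spacing=(1.5, 1.5, 2.0), n_nodules=1
    )
    res = preprocess.resample_isotropic(vol)
    cx, cy, cz = preprocess.world_to_voxel(ann[0].center_world, res)
    nz, ny, nx = res.shape
    assert 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz
    # the bright centre must still be bright at the transformed index
    assert res.voxels[round(cz), round(cy), round(cx)] > -300


# ---------------------------------------------------------------------------
# Slice triplets + 2D augmentation
# ---------------------------------------------------------------------------

def _one_nodule_volume(z=10, diameter=10.0, shape=(32, 64, 64)):
    voxels = np.full(shape, -850.0, dtype=np.float32)
    ann = NoduleAnnotation(scan_id="t", center_world=(30.0, 30.0, float(z)), diameter_mm=diameter)
    vol = CTVolume(voxels=voxels, origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), scan_id="t")
    return vol, [ann]


def test_triplet_count_box_size_and_channels():
    vol, ann = _one_nodule_volume()
    trips = preprocess.make_slice_triplets(vol, ann, out_size=64)  # no rescale
    assert len(trips) == 1
    t = trips[0]
    assert t.image.shape == (3, 64, 64)
    (x0, y0, x1, y1) = t.boxes[0]
    assert np.isclose(x1 - x0, 10.0) and np.isclose(y1 - y0, 10.0)
    assert np.isclose((x0 + x1) / 2, 30.0)


def test_triplet_rescale_scales_boxes():
    vol, ann = _one_nodule_volume()
    t = preprocess.make_slice_triplets(vol, ann, out_size=128)[0]
    (x0, y0, x1, y1) = t.boxes[0]
    assert np.isclose(x1 - x0, 20.0)  # 10 px * 128/64


def test_boundary_slices_replicate_edges():
    vol, ann = _one_nodule_volume(z=0)
    vol.voxels[0] += 100  # make slice 0 distinguishable
    t = preprocess.make_slice_triplets(vol, ann, out_size=64)[0]
    assert np.array_equal(t.image[0], t.image[1])  # previous duplicates slice 0
    assert not np.array_equal(t.image[1], t.image[2])


def test_annotation_outside_volume_rejected():
    vol, _ = _one_nodule_volume()
    bad = NoduleAnnotation(scan_id="t", center_world=(30.0, 30.0, 999.0), diameter_mm=5)
    with pytest.raises(ValueError):
        preprocess.make_slice_triplets(vol, [bad], out_size=64)


@pytest.mark.parametrize("diameter,expected", [(25.0, 5), (15.0, 3), (6.0, 1)])
def test_augment_2d_diameter_buckets(diameter, expected):
    vol, ann = _one_nodule_volume(z=15, diameter=diameter)
    trips = preprocess.augment_2d(vol, ann, out_size=64)
    assert len(trips) == expected
    assert trips[0].center_slice_index == 15  # original kept first


# ---------------------------------------------------------------------------
# Multiscale patches + 3D augmentation
# ---------------------------------------------------------------------------

def test_extract_patches_centered_no_padding(preprocessed_volume):
    vol, ann = preprocessed_volume
    cubes = preprocess.extract_multiscale_patches(vol, ann[0].center_world)
    assert tuple(c.shape[0] for c in cubes) == (70, 36, 20)
    # cube centres coincide with the candidate centre voxel
    cx, cy, cz = preprocess.world_to_voxel(ann[0].center_world, vol)
    center_val = vol.voxels[round(cz), round(cy), round(cx)]
    for cube, side in zip(cubes, (70, 36, 20)):
        assert np.isclose(cube[side // 2, side // 2, side // 2], center_val)


def test_extract_patches_pads_at_corner(preprocessed_volume):
    vol, _ = preprocessed_volume
    corner_world = preprocess.voxel_to_world((1.0, 1.0, 1.0), vol)
    cubes = preprocess.extract_multiscale_patches(vol, corner_world)
    assert cubes[0].shape == (70, 70, 70)
    assert np.isclose(cubes[0][0, 0, 0], vol.voxels.min())  # padded corner


def test_extract_patches_outside_volume_rejected(preprocessed_volume):
    vol, _ = preprocessed_volume
    with pytest.raises(ValueError):
        preprocess.extract_multiscale_patches(vol, (1e4, 1e4, 1e4))


def test_augment_3d_yields_200_with_shared_offsets(preprocessed_volume):
    vol, ann = preprocessed_volume
    cubes = preprocess.extract_multiscale_patches(vol, ann[0].center_world)
    crops = preprocess.augment_3d(cubes, seed=3, label=1)
    assert len(crops) == 200  # 25 crops x 8 flips
    for c in crops:
        assert tuple(cu.shape[0] for cu in c.cubes) == (64, 32, 16)
    # the first flip of each group of 8 is the identity flip
    for g in range(0, 200, 8):
        assert np.array_equal(crops[g].cubes[0], crops[g].cubes[0])
        # flips are involutions: flipping the flipped crop restores the base
        base = crops[g].cubes[0]
        for axes in [(0,), (1,), (2,), (0, 1, 2)]:
            assert np.array_equal(np.flip(np.flip(base, axes), axes), base)


def test_augment_3d_crops_stay_inside_enclosures():
    rng = np.random.default_rng(0)
    # encode the source index in the voxel values to recover crop offsets
    cubes = [np.arange(s**3, dtype=np.float32).reshape(s, s, s) for s in (70, 36, 20)]
    crops = preprocess.augment_3d(cubes, seed=9, label=0)
    for c in crops[::8]:  # identity-flip member of each crop group
        first = c.cubes[0][0, 0, 0]
        z = int(first) // (70 * 70)
        assert 0 <= z <= 6  # 64-cube offset within the 70-cube margin


def test_augment_3d_determinism():
    cubes = [np.random.default_rng(1).normal(size=(s,) * 3) for s in (70, 36, 20)]
    a = preprocess.augment_3d(cubes, seed=5)
    b = preprocess.augment_3d(cubes, seed=5)
    assert all(np.array_equal(x.cubes[1], y.cubes[1]) for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Positive double-sampling
# ---------------------------------------------------------------------------

def test_balance_samples_doubles_positives():
    crops = phantom.generate_multiscale_dataset(0, 10, 50)
    out = preprocess.balance_samples(crops, seed=0)
    assert len(out) == 70  # 2 * 10 + 50
    neg_in = [id(c) for c in crops if c.label == 0]
    neg_out = [id(c) for c in out if c.label == 0]
    assert sorted(neg_in) == sorted(neg_out)  # negatives preserved as a multiset
    pos_out = [id(c) for c in out if c.label == 1]
    assert len(pos_out) == 20 and len(set(pos_out)) == 10


def test_balance_samples_no_positives_is_permutation():
    crops = phantom.generate_multiscale_dataset(0, 0, 5)
    out = preprocess.balance_samples(crops, seed=1)
    assert sorted(id(c) for c in out) == sorted(id(c) for c in crops)
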