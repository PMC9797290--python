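"""CT preprocessing for the two detection stages.

Pipeline order is fixed: intensity clip -> Z-score normalisation ->
coordinate transform -> isotropic resampling -> cropping. The operations are
exposed separately so each is testable, but :func:`preprocess_volume` applies
them in that order.

Stage-one inputs are three-channel "slice triplets" (the nodule-centred
axial slice with its two neighbours). Stage-two inputs are co-centred 3D
patches at three physical extents, augmented 25x by random crops and 8x by
axis flips (200 samples per candidate).
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import CTVolume, MultiscaleCrop, NoduleAnnotation, SliceTriplet

__all__ = [
    "HU_WINDOW",
    "clip_hu",
    "zscore",
    "world_to_voxel",
    "voxel_to_world",
    "resample_isotropic",
    "preprocess_volume",
    "make_slice_triplets",
    "augment_2d",
    "extract_multiscale_patches",
    "augment_3d",
    "balance_samples",
    "ENCLOSING_SIDES",
    "CROP_SIDES",
]

HU_WINDOW = (-1200.0, 600.0)
ENCLOSING_SIDES = (70, 36, 20)
CROP_SIDES = (64, 32, 16)
N_RANDOM_CROPS = 25


def clip_hu(voxels: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    """Clamp intensities into the lung window (default [-1200, 600] HU)."""
    return np.clip(voxels, window[0], window[1])


def zscore(voxels: np.ndarray) -> np.ndarray:
    """Standardise to zero mean / unit standard deviation (per volume)."""
    voxels = np.asarray(voxels, dtype=np.float64)
    sd = voxels.std()
    if sd == 0:
        raise ValueError("cannot Z-score a constant-intensity volume")
    return ((voxels - voxels.mean()) / sd).astype(np.float32)


def world_to_voxel(
    p_world: Sequence[float], vol: CTVolume
) -> tuple[float, float, float]:
    """World mm -> continuous voxel index, both in (x, y, z) order."""
    return tuple(
        (float(p) - o) / s for p, o, s in zip(p_world, vol.origin, vol.spacing)
    )


def voxel_to_world(
    p_voxel: Sequence[float], vol: CTVolume
) -> tuple[float, float, float]:
    """Continuous voxel index -> world mm, both in (x, y, z) order."""
    return tuple(
        o + float(p) * s for p, o, s in zip(p_voxel, vol.origin, vol.spacing)
    )


def resample_isotropic(
    vol: CTVolume, target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> CTVolume:
    """Trilinearly resample to the target spacing (default 1 mm isotropic).

    The output shape is ``round(shape * spacing / target)`` per axis and the
    world position of any structure is preserved (its voxel index changes).
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    if np.allclose(vol.spacing, target_spacing):
        return CTVolume(
            voxels=vol.voxels.copy(),
            origin=vol.origin,
            spacing=tuple(target_spacing),
            scan_id=vol.scan_id,
        )
    spacing_zyx = np.array(vol.spacing[::-1])
    target_zyx = np.array(target_spacing[::-1])
    out_shape = np.round(np.array(vol.voxels.shape) * spacing_zyx / target_zyx).astype(int)
    out_shape = np.maximum(out_shape, 1)
    factors = out_shape / np.array(vol.voxels.shape)
    resampled = ndimage.zoom(
        vol.voxels.astype(np.float32), factors, order=1, mode="nearest", grid_mode=True
    )
    # grid_mode=True treats voxels as cells, but zoom only guarantees the
    # factor, not the rounded shape, exactly; trim/pad the odd edge voxel.
    resampled = resampled[: out_shape[0], : out_shape[1], : out_shape[2]]
    return CTVolume(
        voxels=resampled,
        origin=vol.origin,
        spacing=tuple(target_spacing),
        scan_id=vol.scan_id,
    )


def preprocess_volume(
    vol: CTVolume,
    window: tuple[float, float] = HU_WINDOW,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CTVolume:
    """Apply the full intensity + geometry pipeline: clip, Z-score, resample."""
    clipped = clip_hu(vol.voxels, window)
    normalised = zscore(clipped)
    staged = CTVolume(
        voxels=normalised, origin=vol.origin, spacing=vol.spacing, scan_id=vol.scan_id
    )
    return resample_isotropic(staged, target_spacing)


def _resize2d(img: np.ndarray, out_size: int) -> np.ndarray:
    if img.shape == (out_size, out_size):
        return img.astype(np.float32)
    factors = (out_size / img.shape[0], out_size / img.shape[1])
    return ndimage.zoom(img.astype(np.float32), factors, order=1, mode="nearest")[
        :out_size, :out_size
    ]


def _triplet_at(
    vol: CTVolume,
    annotations: Sequence[NoduleAnnotation],
    center_index: int,
    out_size: int,
) -> SliceTriplet:
    nz, ny, nx = vol.voxels.shape
    idx = [max(0, min(nz - 1, center_index + d)) for d in (-1, 0, 1)]
    channels = np.stack([_resize2d(vol.voxels[i], out_size) for i in idx])
    scale_x = out_size / nx
    scale_y = out_size / ny
    boxes = []
    for ann in annotations:
        cx, cy, cz = world_to_voxel(ann.center_world, vol)
        rz = ann.diameter_mm / (2.0 * vol.spacing[2])
        if abs(cz - center_index) > max(rz, 0.5):
            continue  # nodule does not reach this slice
        wx = ann.diameter_mm / vol.spacing[0] * scale_x
        wy = ann.diameter_mm / vol.spacing[1] * scale_y
        boxes.append(
            (
                cx * scale_x - wx / 2,
                cy * scale_y - wy / 2,
                cx * scale_x + wx / 2,
                cy * scale_y + wy / 2,
            )
        )
    return SliceTriplet(
        image=channels, scan_id=vol.scan_id, center_slice_index=center_index, boxes=boxes
    )


def make_slice_triplets(
    vol: CTVolume,
    annotations: Sequence[NoduleAnnotation],
    out_size: int = 512,
) -> list[SliceTriplet]:
    """One nodule-centred triplet per annotation.

    The centre channel is the axial slice through the nodule centre; the
    neighbours are the adjacent slices (edge slices replicated at volume
    boundaries). In-plane content is rescaled to ``out_size`` squared and the
    ground-truth box side equals the diameter divided by the effective
    in-plane spacing after the rescale.
    """
    triplets = []
    nz, ny, nx = vol.voxels.shape
    for ann in annotations:
        cx, cy, cz = world_to_voxel(ann.center_world, vol)
        if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
            raise ValueError(
                f"annotation at voxel ({cx:.1f}, {cy:.1f}, {cz:.1f}) outside volume"
            )
        triplets.append(_triplet_at(vol, annotations, int(round(cz)), out_size))
    return triplets


def augment_2d(
    vol: CTVolume,
    annotations: Sequence[NoduleAnnotation],
    out_size: int = 512,
) -> list[SliceTriplet]:
    """Diameter-bucketed slice augmentation for stage-one training.

    Per nodule the original centred triplet is kept and extra triplets are
    added at neighbouring centre slices: diameters > 20 mm get four extras
    (offsets +-1 and +-2), 10-20 mm get two (+-1), <= 10 mm get none.
    """
    out: list[SliceTriplet] = []
    nz = vol.voxels.shape[0]
    for ann in annotations:
        _, _, cz = world_to_voxel(ann.center_world, vol)
        ci = int(round(cz))
        if not 0 <= ci < nz:
            raise ValueError("annotation outside volume")
        if ann.diameter_mm > 20:
            offsets = (0, -2, -1, 1, 2)
        elif ann.diameter_mm > 10:
            offsets = (0, -1, 1)
        else:
            offsets = (0,)
        for off in offsets:
            out.append(
                _triplet_at(vol, annotations, max(0, min(nz - 1, ci + off)), out_size)
            )
    return out


def extract_multiscale_patches(
    vol: CTVolume,
    candidate_center_world: Sequence[float],
    sides: Sequence[int] = ENCLOSING_SIDES,
    pad_value: Optional[float] = None,
) -> tuple[np.ndarray, ...]:
    """Cut co-centred enclosing cubes (default 70/36/20 voxels) at a candidate.

    Requires a 1 mm isotropic volume. Out-of-bounds regions are padded with
    the lung-window minimum (or its normalised equivalent when the volume is
    already standardised).
    """
    cx, cy, cz = world_to_voxel(candidate_center_world, vol)
    nz, ny, nx = vol.voxels.shape
    if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
        raise ValueError("candidate centre outside volume")
    if pad_value is None:
        # Heuristic: a standardised volume has |values| of order 1.
        pad_value = HU_WINDOW[0] if vol.voxels.min() < -10 else float(vol.voxels.min())
    center = np.array([cz, cy, cx])
    cubes = []
    for side in sides:
        lo = np.round(center).astype(int) - side // 2
        hi = lo + side
        cube = np.full((side,) * 3, pad_value, dtype=np.float32)
        src_lo = np.maximum(lo, 0)
        src_hi = np.minimum(hi, vol.voxels.shape)
        dst_lo = src_lo - lo
        dst_hi = dst_lo + (src_hi - src_lo)
        if np.all(src_hi > src_lo):
            cube[
                dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]
            ] = vol.voxels[src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]]
        cubes.append(cube)
    return tuple(cubes)


def _flip(cube: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    return np.flip(cube, axis=axes).copy() if axes else cube.copy()


def augment_3d(
    cubes: Sequence[np.ndarray],
    seed: int,
    label: int = 1,
    scan_id: str = "",
    center_world: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_crops: int = N_RANDOM_CROPS,
) -> list[MultiscaleCrop]:
    """Stage-two augmentation: 25 seeded random crops x 8 axis flips = 200.

    Each crop uses one fractional offset shared across the three scales, so
    the 64/32/16 crops stay co-registered within their 70/36/20 enclosures.
    The 8 flips are all subsets of {flip-z, flip-y, flip-x}; the empty subset
    reproduces the unflipped crop.
    """
    if len(cubes) != len(ENCLOSING_SIDES):
        raise ValueError(f"expected {len(ENCLOSING_SIDES)} enclosing cubes")
    for cube, side in zip(cubes, ENCLOSING_SIDES):
        if cube.shape != (side,) * 3:
            raise ValueError(f"expected a {side}^3 cube, got {cube.shape}")
    rng = np.random.default_rng(seed)
    margins = [e - c for e, c in zip(ENCLOSING_SIDES, CROP_SIDES)]
    out: list[MultiscaleCrop] = []
    for _ in range(n_crops):
        frac = rng.uniform(0.0, 1.0, size=3)  # shared across scales
        crops = []
        for cube, margin, side in zip(cubes, margins, CROP_SIDES):
            off = np.floor(frac * (margin + 1)).astype(int)
            off = np.minimum(off, margin)
            crops.append(
                cube[off[0] : off[0] + side, off[1] : off[1] + side, off[2] : off[2] + side]
            )
        for axes in itertools.chain.from_iterable(
            itertools.combinations((0, 1, 2), r) for r in range(4)
        ):
            out.append(
                MultiscaleCrop(
                    cubes=tuple(_flip(c, axes) for c in crops),
                    label=label,
                    scan_id=scan_id,
                    center_world=center_world,
                )
            )
    return out


def balance_samples(samples: Sequence, seed: int = 0) -> list:
    """Double-sample positives (label 1), keep negatives once, shuffle.

    Works for any sample type with a ``label`` attribute.
    """
    out = []
    for s in samples:
        out.append(s)
        if s.label == 1:
            out.append(s)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(out))
    return [out[i] for i in order]
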