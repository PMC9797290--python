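"""Seeded synthetic CT phantoms with annotated nodules and distractors.

The generator emulates the statistics the pipeline is built around: lung-like
background around -850 HU, quasi-spherical soft-tissue nodules with diameters
in the 3-40 mm range, vessel-like tube distractors that are *not* annotated,
and a matching world-coordinate annotation list. Every function is a pure
function of its seed and parameters, so downstream stages are testable
without external scan data.

A ``difficulty`` knob in [0, 1] linearly shrinks the nodule/background
contrast: at 0 the patch classes are separable by a single mean-intensity
threshold, at 1 nodules match the background mean.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import CTVolume, MultiscaleCrop, NoduleAnnotation, PatchSample

__all__ = [
    "generate_volume",
    "generate_patch_dataset",
    "generate_multiscale_dataset",
    "HU_BACKGROUND_MEAN",
    "HU_BACKGROUND_NOISE_SD",
    "HU_NODULE_RANGE",
    "DIAMETER_RANGE_MM",
]

# Intensity model constants (HU). Overridable per call where exposed.
HU_BACKGROUND_MEAN = -850.0
HU_BACKGROUND_NOISE_SD = 30.0
HU_BACKGROUND_FIELD_AMP = 40.0  # smooth low-frequency drift
HU_NODULE_RANGE = (-50.0, 100.0)  # soft tissue
HU_VESSEL_RANGE = (-300.0, -100.0)
DIAMETER_RANGE_MM = (3.0, 40.0)

_EDGE_MM = 0.6  # soft-edge width of the nodule boundary


def _background(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """Lung-like background: broadband noise plus a smooth drift field."""
    vol = rng.normal(HU_BACKGROUND_MEAN, HU_BACKGROUND_NOISE_SD, size=shape)
    # Low-frequency field from a coarse grid, trilinearly upsampled.
    coarse_shape = tuple(max(2, s // 16) for s in shape)
    coarse = rng.normal(0.0, HU_BACKGROUND_FIELD_AMP, size=coarse_shape)
    from scipy.ndimage import zoom

    factors = [s / c for s, c in zip(shape, coarse_shape)]
    vol += zoom(coarse, factors, order=1)[: shape[0], : shape[1], : shape[2]]
    # Clamp excursions so a nodule-free phantom stays firmly sub-lung-tissue.
    return np.minimum(vol, -550.0)


def _radial_perturbation(rng: np.random.Generator) -> np.ndarray:
    """Coefficients of a low-order angular perturbation of the radius."""
    return rng.uniform(-0.12, 0.12, size=6)


def _paint_blob(
    voxels: np.ndarray,
    center_vox: np.ndarray,  # (z, y, x), continuous
    radius_mm: float,
    spacing_zyx: np.ndarray,
    hu: float,
    coeffs: np.ndarray,
) -> None:
    """Add a quasi-spherical soft-edged blob in place.

    The surface radius is ``radius_mm * (1 + low-order angular terms)``; the
    intensity blends from background to ``hu`` over a ~0.6 mm sigmoid edge.
    """
    margin = radius_mm * 1.3 + 3.0 * _EDGE_MM
    lo = np.maximum(np.floor(center_vox - margin / spacing_zyx).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + margin / spacing_zyx).astype(int) + 1, voxels.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
    )
    d_mm = np.stack(
        [(g - c) * s for g, c, s in zip((zz, yy, xx), center_vox, spacing_zyx)]
    )
    dist = np.sqrt((d_mm**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(dist > 0, d_mm / np.maximum(dist, 1e-9), 0.0)
    uz, uy, ux = u
    # Low-order even/odd angular terms keep the shape non-trivially round.
    pert = (
        coeffs[0] * ux
        + coeffs[1] * uy
        + coeffs[2] * uz
        + coeffs[3] * (ux * uy)
        + coeffs[4] * (uy * uz)
        + coeffs[5] * (3 * uz**2 - 1) / 2
    )
    surface = radius_mm * (1.0 + pert)
    weight = 1.0 / (1.0 + np.exp(np.clip((dist - surface) / _EDGE_MM, -40, 40)))
    region = voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    region += weight * (hu - region)


def _paint_tube(
    voxels: np.ndarray,
    rng: np.random.Generator,
    spacing_zyx: np.ndarray,
    hu: float,
) -> None:
    """Paint a vessel-like tube as a chain of small overlapping blobs."""
    shape = np.array(voxels.shape, dtype=float)
    start = rng.uniform(0.1, 0.9, size=3) * shape
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    length_mm = rng.uniform(15.0, 50.0)
    radius_mm = rng.uniform(0.5, 1.6)
    n_steps = max(2, int(length_mm / min(radius_mm, 2.0)))
    coeffs = np.zeros(6)
    for t in np.linspace(0.0, 1.0, n_steps):
        center = start + direction * (t * length_mm) / spacing_zyx
        if np.any(center < 0) or np.any(center >= shape):
            continue
        _paint_blob(voxels, center, radius_mm, spacing_zyx, hu, coeffs)


def generate_volume(
    seed: int,
    shape: tuple[int, int, int] = (64, 128, 128),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_nodules: int = 3,
    n_distractors: int = 0,
    *,
    diameters_mm: Optional[Sequence[float]] = None,
    difficulty: float = 0.0,
    origin: tuple[float, float, float] = (-200.0, -200.0, -300.0),
    scan_id: Optional[str] = None,
) -> tuple[CTVolume, list[NoduleAnnotation]]:
    """Generate a phantom CT volume plus its nodule annotations.

    Parameters
    ----------
    seed
        Seeds all randomness; identical calls are bit-identical.
    shape
        Voxel counts ``(z, y, x)``, each >= 32.
    spacing
        Voxel size in mm, ``(x, y, z)`` order, strictly positive.
    n_nodules, n_distractors
        Number of annotated nodules and of unannotated distractor structures.
    diameters_mm
        Optional explicit nodule diameters; otherwise sampled uniformly from
        the 3-40 mm range (upper end capped so the nodule fits).
    difficulty
        0 = full soft-tissue contrast, 1 = nodules vanish into background.

    Returns
    -------
    (CTVolume, list of NoduleAnnotation) with annotation centres in world mm.
    """
    if any(s < 32 for s in shape):
        raise ValueError(f"each shape axis must be >= 32, got {shape}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    if n_nodules < 0 or n_distractors < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must lie in [0, 1]")
    if diameters_mm is not None and len(diameters_mm) != n_nodules:
        raise ValueError("diameters_mm length must equal n_nodules")

    rng = np.random.default_rng(seed)
    spacing_zyx = np.array(spacing[::-1], dtype=float)
    extent_mm = np.array(shape) * spacing_zyx  # (z, y, x) physical extent
    voxels = _background(rng, tuple(shape))

    # Largest diameter whose placement margin (1.3 x radius + 2 mm for the
    # perturbed soft edge) still fits inside the shortest axis.
    d_max_fit = float((min(extent_mm) - 5.0) / 1.3)
    annotations: list[NoduleAnnotation] = []
    scan_id = scan_id if scan_id is not None else f"phantom-{seed:06d}"
    centers_vox: list[np.ndarray] = []

    for i in range(n_nodules):
        if diameters_mm is not None:
            d = float(diameters_mm[i])
            if not DIAMETER_RANGE_MM[0] <= d <= DIAMETER_RANGE_MM[1]:
                raise ValueError(f"diameter {d} outside {DIAMETER_RANGE_MM} mm")
            if d > d_max_fit:
                raise ValueError(f"nodule of {d} mm cannot fit inside volume")
        else:
            if d_max_fit < DIAMETER_RANGE_MM[0]:
                raise ValueError("volume too small for the minimum 3 mm nodule")
            d = float(rng.uniform(DIAMETER_RANGE_MM[0], min(DIAMETER_RANGE_MM[1], d_max_fit)))
        margin_vox = (d / 2 * 1.3 + 2.0) / spacing_zyx
        # Rejection-sample a centre keeping nodules reasonably separated.
        for _ in range(200):
            center = np.array(
                [rng.uniform(m, s - 1 - m) for m, s in zip(margin_vox, shape)]
            )
            if all(
                np.linalg.norm((center - c) * spacing_zyx) > (d / 2 + a.diameter_mm / 2 + 4.0)
                for c, a in zip(centers_vox, annotations)
            ):
                break
        hu = float(rng.uniform(*HU_NODULE_RANGE))
        hu = hu + difficulty * (HU_BACKGROUND_MEAN - hu)
        _paint_blob(voxels, center, d / 2, spacing_zyx, hu, _radial_perturbation(rng))
        centers_vox.append(center)
        # world (x, y, z) = origin + voxel_index * spacing
        world = tuple(
            origin[ax] + center[::-1][ax] * spacing[ax] for ax in range(3)
        )
        annotations.append(
            NoduleAnnotation(scan_id=scan_id, center_world=world, diameter_mm=d)
        )

    for _ in range(n_distractors):
        kind = rng.uniform()
        hu = float(rng.uniform(*HU_VESSEL_RANGE))
        hu = hu + difficulty * (HU_BACKGROUND_MEAN - hu)
        if kind < 0.6:
            _paint_tube(voxels, rng, spacing_zyx, hu)
        else:
            # Sub-annotation-size or low-contrast blob.
            center = rng.uniform(4, np.array(shape, dtype=float) - 5)
            radius = rng.uniform(0.5, 1.4)
            _paint_blob(voxels, center, radius, spacing_zyx, hu, _radial_perturbation(rng))

    vol = CTVolume(
        voxels=np.round(voxels).astype(np.int16),
        origin=origin,
        spacing=spacing,
        scan_id=scan_id,
    )
    return vol, annotations


def _patch_stack(
    rng: np.random.Generator, positive: bool, difficulty: float
) -> np.ndarray:
    """One 64-mm^3 local field at 1 mm spacing; positives get a centred blob."""
    side = 64
    cube = rng.normal(HU_BACKGROUND_MEAN, HU_BACKGROUND_NOISE_SD, size=(side,) * 3)
    spacing = np.ones(3)
    if positive:
        d = rng.uniform(6.0, 13.0)
        hu = float(rng.uniform(*HU_NODULE_RANGE))
        hu = hu + difficulty * (HU_BACKGROUND_MEAN - hu)
        jitter = rng.uniform(-1.5, 1.5, size=3)
        _paint_blob(
            cube,
            np.full(3, (side - 1) / 2) + jitter,
            d / 2,
            spacing,
            hu,
            _radial_perturbation(rng),
        )
    elif rng.uniform() < 0.5:
        # Faint distractor texture so negatives are not pure noise.
        hu = float(rng.uniform(-650.0, -500.0))
        hu = hu + difficulty * (HU_BACKGROUND_MEAN - hu)
        center = rng.uniform(10, side - 11, size=3)
        _paint_blob(cube, center, rng.uniform(0.5, 1.5), spacing, hu, _radial_perturbation(rng))
    return cube


def _center_crop(cube: np.ndarray, side: int) -> np.ndarray:
    start = (cube.shape[0] - side) // 2
    sl = slice(start, start + side)
    return cube[sl, sl, sl]


def generate_patch_dataset(
    seed: int,
    n_pos: int,
    n_neg: int,
    sides: Sequence[int] = (16, 32, 64),
    *,
    difficulty: float = 0.0,
) -> list[PatchSample]:
    """Generate labelled cubic patches, one :class:`PatchSample` per side.

    Positive cubes contain a centred-ish soft-tissue blob; negative cubes are
    background (sometimes with faint distractor texture). At ``difficulty`` 0
    the classes are separable by mean intensity alone.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    bad = [s for s in sides if s not in (16, 32, 64)]
    if bad:
        raise ValueError(f"sides must be drawn from {{16, 32, 64}}, got {bad}")
    rng = np.random.default_rng(seed)
    samples: list[PatchSample] = []
    for label in (1,) * n_pos + (0,) * n_neg:
        field = _patch_stack(rng, positive=bool(label), difficulty=difficulty)
        for side in sides:
            samples.append(
                PatchSample(cube=_center_crop(field, side).copy(), side=side, label=label)
            )
    return samples


def generate_multiscale_dataset(
    seed: int,
    n_pos: int,
    n_neg: int,
    *,
    difficulty: float = 0.0,
) -> list[MultiscaleCrop]:
    """Generate co-centred (64, 32, 16) cube triples for the 3D classifier."""
    rng = np.random.default_rng(seed)
    crops: list[MultiscaleCrop] = []
    for label in (1,) * n_pos + (0,) * n_neg:
        field = _patch_stack(rng, positive=bool(label), difficulty=difficulty)
        crops.append(
            MultiscaleCrop(
                cubes=(field, _center_crop(field, 32).copy(), _center_crop(field, 16).copy()),
                label=int(label),
            )
        )
    return crops
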