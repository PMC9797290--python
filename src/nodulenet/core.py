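"""Core data containers shared across the pipeline.

Conventions (matching the MetaImage / LUNA16 dialects):

* voxel arrays are indexed ``(z, y, x)``;
* ``origin`` and ``spacing`` are stored ``(x, y, z)`` in millimetres;
* world coordinates are axis-aligned: ``world = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CTVolume",
    "NoduleAnnotation",
    "PatchSample",
    "Detection",
    "MultiscaleCrop",
    "SliceTriplet",
]


@dataclass
class CTVolume:
    """A CT-like intensity volume in Hounsfield units with world metadata.

    Parameters
    ----------
    voxels
        3D array indexed ``(z, y, x)``.
    origin
        World position (mm) of voxel ``(0, 0, 0)``, in ``(x, y, z)`` order.
    spacing
        Voxel edge lengths (mm), ``(x, y, z)`` order, all strictly positive.
    scan_id
        Opaque identifier (the LUNA16 ``seriesuid`` slot).
    """

    voxels: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if len(self.origin) != 3 or len(self.spacing) != 3:
            raise ValueError("origin and spacing must be (x, y, z) triples")
        if not all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")
        if any(s <= 0 or not np.isfinite(s) for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape, ``(z, y, x)``."""
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class NoduleAnnotation:
    """A nodule ground-truth mark: world-space centre and diameter in mm."""

    scan_id: str
    center_world: tuple[float, float, float]  # (x, y, z) mm
    diameter_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_world", tuple(float(v) for v in self.center_world))
        object.__setattr__(self, "diameter_mm", float(self.diameter_mm))
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")


@dataclass
class PatchSample:
    """A labelled cubic 3D patch used to train/evaluate the FP filter."""

    cube: np.ndarray
    side: int
    label: int  # 1 = nodule, 0 = non-nodule
    source_annotation: Optional[NoduleAnnotation] = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        if self.cube.shape != (self.side,) * 3:
            raise ValueError(
                f"cube shape {self.cube.shape} does not match side {self.side}"
            )
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class MultiscaleCrop:
    """Co-centred cubes at sides (64, 32, 16) feeding the three-branch 3D CNN."""

    cubes: tuple[np.ndarray, np.ndarray, np.ndarray]  # sides 64, 32, 16
    label: int
    scan_id: str = ""
    center_world: tuple[float, float, float] = (0.0, 0.0, 0.0)

    EXPECTED_SIDES = (64, 32, 16)

    def __post_init__(self) -> None:
        if len(self.cubes) != 3:
            raise ValueError("exactly three cubes required")
        for cube, side in zip(self.cubes, self.EXPECTED_SIDES):
            if cube.shape != (side,) * 3:
                raise ValueError(f"expected a {side}^3 cube, got {cube.shape}")


@dataclass
class SliceTriplet:
    """Three adjacent axial slices stacked as a 3-channel 2D image.

    ``boxes`` are ground-truth 2D boxes in pixel coordinates,
    ``(x_min, y_min, x_max, y_max)``, 0-based and half-open.
    """

    image: np.ndarray  # (3, H, W): previous, centre, next slice
    scan_id: str
    center_slice_index: int
    boxes: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError("image must be (3, H, W)")


@dataclass
class Detection:
    """One detector output: a scored 2D box with scan/slice provenance."""

    scan_id: str
    slice_index: int
    box: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max (pixels)
    score: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
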