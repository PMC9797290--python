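"""MetaImage (.mhd/.raw) volume I/O and LUNA16-dialect annotation CSV I/O.

The MetaImage writer emits an uncompressed two-file pair: a text header and a
little-endian 16-bit signed raw block, which is the dialect LUNA16 ships.
Only the keys this pipeline relies on are interpreted; unknown header keys
are ignored on read.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import CTVolume, NoduleAnnotation

__all__ = [
    "MetaImageParseError",
    "write_volume",
    "read_volume",
    "write_annotations",
    "read_annotations",
    "ANNOTATION_COLUMNS",
]

ANNOTATION_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"]

_REQUIRED_KEYS = ("NDims", "DimSize", "ElementSpacing", "Offset", "ElementType", "ElementDataFile")

_MET_TYPES = {
    "MET_SHORT": np.int16,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
    "MET_UCHAR": np.uint8,
    "MET_INT": np.int32,
}


class MetaImageParseError(ValueError):
    """Raised when a .mhd header is missing a required key or is malformed."""


def write_volume(vol: CTVolume, path: str | os.PathLike, dtype=np.int16) -> None:
    """Write ``vol`` as an .mhd header plus a sibling .raw block.

    ``path`` names the header; the raw file shares its stem. Intensities are
    stored as little-endian ``dtype`` (default int16, the CT-native choice).
    """
    path = Path(path)
    if path.suffix != ".mhd":
        path = path.with_suffix(".mhd")
    raw_name = path.with_suffix(".raw").name
    nz, ny, nx = vol.voxels.shape
    met_type = {v: k for k, v in _MET_TYPES.items()}[np.dtype(dtype).type]
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {vol.origin[0]:.6f} {vol.origin[1]:.6f} {vol.origin[2]:.6f}",
        "CenterOfRotation = 0 0 0",
        "AnatomicalOrientation = RAI",
        f"ElementSpacing = {vol.spacing[0]:.6f} {vol.spacing[1]:.6f} {vol.spacing[2]:.6f}",
        f"DimSize = {nx} {ny} {nz}",
        f"ElementType = {met_type}",
        f"ElementDataFile = {raw_name}",
    ]
    path.write_text("\n".join(header) + "\n")
    data = np.ascontiguousarray(vol.voxels, dtype=np.dtype(dtype).newbyteorder("<"))
    data.tofile(path.with_suffix(".raw"))


def _parse_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if "=" not in line:
            raise MetaImageParseError(f"malformed header line: {line!r}")
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    return fields


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read an .mhd/.raw pair back into a :class:`CTVolume`."""
    path = Path(path)
    fields = _parse_header(path.read_text())
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise MetaImageParseError(f"header missing required key {key!r}")
    if fields["NDims"] != "3":
        raise MetaImageParseError(f"expected NDims = 3, got {fields['NDims']}")
    try:
        dtype = _MET_TYPES[fields["ElementType"]]
    except KeyError:
        raise MetaImageParseError(f"unsupported ElementType {fields['ElementType']!r}")
    nx, ny, nz = (int(v) for v in fields["DimSize"].split())
    spacing = tuple(float(v) for v in fields["ElementSpacing"].split())
    origin = tuple(float(v) for v in fields["Offset"].split())
    raw_path = path.parent / fields["ElementDataFile"]
    data = np.fromfile(raw_path, dtype=np.dtype(dtype).newbyteorder("<"))
    if data.size != nx * ny * nz:
        raise MetaImageParseError(
            f"raw block has {data.size} elements, header promises {nx * ny * nz}"
        )
    voxels = data.reshape(nz, ny, nx)
    return CTVolume(voxels=voxels, origin=origin, spacing=spacing, scan_id=path.stem)


def write_annotations(annotations: Iterable[NoduleAnnotation], path: str | os.PathLike) -> None:
    """Write annotations as the LUNA16 CSV dialect."""
    rows = [
        {
            "seriesuid": a.scan_id,
            "coordX": a.center_world[0],
            "coordY": a.center_world[1],
            "coordZ": a.center_world[2],
            "diameter_mm": a.diameter_mm,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_annotations(path: str | os.PathLike) -> list[NoduleAnnotation]:
    """Read a LUNA16-dialect annotation CSV."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV missing column(s): {', '.join(missing)}")
    return [
        NoduleAnnotation(
            scan_id=str(row.seriesuid),
            center_world=(row.coordX, row.coordY, row.coordZ),
            diameter_mm=row.diameter_mm,
        )
        for row in df.itertuples()
    ]


def write_candidates(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a candidates table (``seriesuid,coordX,coordY,coordZ,probability``)."""
    cols = ["seriesuid", "coordX", "coordY", "coordZ", "probability"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"candidates table missing column(s): {', '.join(missing)}")
    df[cols].to_csv(path, index=False, float_format="%.6f")


def read_candidates(path: str | os.PathLike) -> pd.DataFrame:
    """Read a candidates CSV in the LUNA16 dialect."""
    df = pd.read_csv(path)
    cols = ["seriesuid", "coordX", "coordY", "coordZ", "probability"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"candidates CSV missing column(s): {', '.join(missing)}")
    df["seriesuid"] = df["seriesuid"].astype(str)
    return df
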