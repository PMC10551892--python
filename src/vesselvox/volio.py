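"""Calibrated 3D volume and tabular I/O.

Conventions used throughout the package
---------------------------------------
* In memory, voxel grids are numpy arrays in ``(z, y, x)`` storage order.
* Physical coordinates and voxel spacings are reported as ``(x, y, z)`` in
  micrometres; the centre of voxel ``(iz, iy, ix)`` sits at
  ``(ix*sx, iy*sy, iz*sz)`` µm (0-based, voxel-centre based).
* Images are written as multi-page TIFF (one page per z slice) with an
  accompanying sidecar JSON (``<stem>.json``) recording the voxel spacing
  and bit depth; spacing is also stored in the ImageJ-style TIFF tags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Volume3D",
    "BinaryMask",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "write_mask",
    "write_segment_table",
    "read_segment_table",
    "write_report",
    "sidecar_path",
]

#: Columns of the per-segment CSV table, in order.
SEGMENT_TABLE_COLUMNS = [
    "id",
    "x0_um",
    "y0_um",
    "z0_um",
    "x1_um",
    "y1_um",
    "z1_um",
    "real_length_um",
    "euclidean_length_um",
    "mean_radius_um",
    "diameter_um",
    "straightness",
    "tortuosity",
]


class VolumeIOError(Exception):
    """Raised when a volume cannot be read or written."""


@dataclass
class Volume3D:
    """A calibrated 3D grayscale image.

    Attributes
    ----------
    values : numpy.ndarray
        Integer gray levels, shape ``(nz, ny, nx)``.
    spacing_um : tuple of float
        Voxel spacing ``(x, y, z)`` in micrometres.
    bit_depth : int
        8 or 16.
    """

    values: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be positive, got {self.spacing_um}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (nz, ny, nx)

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing_um
        return sx * sy * sz

    @property
    def max_gray(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class BinaryMask:
    """A boolean voxel mask sharing the shape and spacing of its source volume."""

    values: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be positive, got {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing_um
        return sx * sy * sz

    def count(self) -> int:
        return int(self.values.sum())


def sidecar_path(path: Path) -> Path:
    """Sidecar metadata JSON next to a TIFF file or slice directory."""
    path = Path(path)
    if path.is_dir():
        return path / "volume.json"
    return path.with_suffix(".json")


def _dtype_for_bit_depth(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8 if bit_depth == 8 else np.uint16)


def read_volume(path: str | Path) -> Volume3D:
    """Read a multi-page TIFF (or a directory of per-slice TIFFs) as a volume.

    Slices in a directory are stacked in lexicographic filename order along z.
    Spacing is taken from the sidecar JSON when present, else defaults to
    (1, 1, 1) µm with a logged warning. Values are preserved bit-exact.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file or directory: {path}")

    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise VolumeIOError(f"directory {path} contains no TIFF slices")
        pages = []
        dtype = None
        for p in slices:
            arr = tifffile.imread(p)
            if arr.ndim == 3 and arr.shape[0] == 1:
                arr = arr[0]
            if arr.ndim != 2:
                raise VolumeIOError(f"non-grayscale or multi-page slice: {p}")
            if dtype is None:
                dtype = arr.dtype
            elif arr.dtype != dtype:
                raise VolumeIOError(
                    f"mixed bit depths: slice {p} has dtype {arr.dtype}, expected {dtype}"
                )
            pages.append(arr)
        values = np.stack(pages, axis=0)
    else:
        values = tifffile.imread(path)
        if values.ndim == 2:
            values = values[None]
        if values.ndim != 3:
            raise VolumeIOError(
                f"{path}: expected grayscale pages, got array of shape {values.shape}"
            )

    if values.dtype == np.uint8:
        bit_depth = 8
    elif values.dtype == np.uint16:
        bit_depth = 16
    else:
        raise VolumeIOError(f"{path}: unsupported dtype {values.dtype} (need uint8/uint16)")

    meta = sidecar_path(path)
    if meta.exists():
        with open(meta) as fh:
            info = json.load(fh)
        spacing = tuple(float(s) for s in info["spacing_um"])
    else:
        logger.warning("no sidecar metadata for %s; assuming 1x1x1 um spacing", path)
        spacing = (1.0, 1.0, 1.0)

    return Volume3D(values=values, spacing_um=spacing, bit_depth=bit_depth)


def write_volume(vol, path: str | Path) -> Path:
    """Write a volume, mask, skeleton or distance map as multi-page TIFF.

    Boolean grids are stored as uint8 {0, 255}; float grids (distance maps)
    as 32-bit float. A sidecar JSON records spacing and kind.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(vol.values)
    spacing = tuple(float(s) for s in vol.spacing_um)

    if values.dtype == bool:
        data = (values.astype(np.uint8)) * 255
        kind = "mask"
        bit_depth = 8
    elif np.issubdtype(values.dtype, np.floating):
        data = values.astype(np.float32)
        kind = "distance"
        bit_depth = 32
    else:
        bit_depth = getattr(vol, "bit_depth", 8)
        data = values.astype(_dtype_for_bit_depth(bit_depth))
        kind = "volume"

    sx, sy, sz = spacing
    try:
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )
    except OSError as exc:
        raise VolumeIOError(f"cannot write {path}: {exc}") from exc

    with open(sidecar_path(path), "w") as fh:
        json.dump({"spacing_um": list(spacing), "bit_depth": bit_depth, "kind": kind}, fh)
    return path


# Masks share the writer; alias kept for readability at call sites.
write_mask = write_volume


def write_segment_table(records: Iterable, path: str | Path) -> Path:
    """Write per-segment morphometric records to CSV (RFC-4180, '.' decimal).

    ``records`` may be SegmentRecord-like objects (attribute access) or dicts.
    An empty record list produces a header-only CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        get = rec.get if isinstance(rec, dict) else lambda k, r=rec: getattr(r, k)
        rows.append({col: get(col) for col in SEGMENT_TABLE_COLUMNS})
    df = pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS)
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise VolumeIOError(f"cannot write {path}: {exc}") from exc
    return path


def read_segment_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    """Recursively convert dataclass-like/np objects into JSON-safe values."""
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(network_md, fits, path: str | Path, extra: dict | None = None) -> Path:
    """Write the network-level descriptor bundle and distribution fits as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"network": _jsonable(network_md), "fits": _jsonable(fits)}
    if extra:
        payload.update(_jsonable(extra))
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    except OSError as exc:
        raise VolumeIOError(f"cannot write {path}: {exc}") from exc
    return path
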