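"""Lossless image-stack I/O: float32 multi-page TIFF or raw, + JSON sidecar.

Every stack or volume on disk is a pair: the voxel data (``<stem>.tif`` as
multi-page float32 TIFF, or ``<stem>.raw`` as raw little-endian float32) and
a ``<stem>.json`` sidecar holding the full acquisition geometry plus the
object kind, tag and intensity convention, so a read reconstructs the
in-memory object exactly (data are stored as float32; arrays round-trip
bitwise at that precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .geometry import TomoGeometry
from .projector import ProjectionStack
from .recon import ReconVolume

__all__ = ["write_stack", "read_stack", "StackFormatError"]


class StackFormatError(RuntimeError):
    """Missing sidecar, truncated data, or an unsupported layout."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(obj, path, fmt: str = "tiff") -> list:
    """Write a ProjectionStack or ReconVolume; returns the files written."""
    path = Path(path)
    if fmt not in ("tiff", "raw"):
        raise ValueError(f"unsupported format {fmt!r}")
    data = np.asarray(obj.data, dtype=np.float32)

    meta = {"geometry": obj.geometry.to_dict(), "shape": list(data.shape), "format": fmt}
    if isinstance(obj, ProjectionStack):
        meta.update(kind="projection_stack", tag=obj.tag, convention=obj.convention)
    elif isinstance(obj, ReconVolume):
        meta.update(
            kind="recon_volume",
            algorithm=obj.algorithm,
            in_focus_index=obj.in_focus_index,
            slice_interval_mm=obj.geometry.slice_interval_mm,
            meta=obj.meta,
        )
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")

    if fmt == "tiff":
        data_path = path.with_suffix(".tif")
        tifffile.imwrite(data_path, data)
    else:
        data_path = path.with_suffix(".raw")
        data.tofile(data_path)

    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=1))
    return [data_path, sidecar]


def read_stack(path):
    """Read back a stack/volume written by ``write_stack``."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise StackFormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    fmt = meta.get("format", "tiff")

    if fmt == "tiff":
        data_path = path.with_suffix(".tif")
        if not data_path.exists():
            raise StackFormatError(f"missing data file {data_path}")
        try:
            data = tifffile.imread(data_path)
        except Exception as exc:  # corrupt container
            raise StackFormatError(f"corrupt TIFF file {data_path}: {exc}") from exc
    else:
        data_path = path.with_suffix(".raw")
        if not data_path.exists():
            raise StackFormatError(f"missing data file {data_path}")
        data = np.fromfile(data_path, dtype=np.float32)
        if data.size != int(np.prod(shape)):
            raise StackFormatError(
                f"truncated raw file {data_path}: {data.size} values, expected {np.prod(shape)}"
            )
        data = data.reshape(shape)

    if tuple(data.shape) != shape:
        raise StackFormatError(
            f"data shape {data.shape} does not match sidecar {shape}"
        )
    if data.dtype not in (np.float32, np.float64):
        import warnings

        warnings.warn(f"converting dtype {data.dtype} to float32", stacklevel=2)
        data = data.astype(np.float32)

    geometry = TomoGeometry.from_dict(meta["geometry"])
    if meta["kind"] == "projection_stack":
        return ProjectionStack(
            data=data, geometry=geometry, tag=meta.get("tag", ""), convention=meta.get("convention", "intensity")
        )
    if meta["kind"] == "recon_volume":
        return ReconVolume(
            data=data,
            geometry=geometry,
            in_focus_index=meta.get("in_focus_index"),
            algorithm=meta.get("algorithm", ""),
            meta=meta.get("meta", {}),
        )
    raise StackFormatError(f"unknown stack kind {meta['kind']!r}")
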