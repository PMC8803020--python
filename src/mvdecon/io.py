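"""Volume and PSF I/O plus JSON configuration plumbing.

Layout convention for multi-page TIFF volumes (documented, fixed):
the page axis is z, the page row axis is y (the rotation axis), and the
page column axis is x.  In memory all volumes are ``(x, y, z)`` arrays, so
reading transposes ``(z, y, x) -> (x, y, z)`` and writing inverts it.

Supported sample formats are 8/16-bit unsigned integers and 32-bit floats.
Integer output is min–max scaled to the full dtype range; the scale and
offset are recorded in the TIFF image description as JSON so values can be
restored.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

__all__ = ["read_volume", "write_volume", "config_from_dict", "config_to_dict"]

_SUPPORTED_DTYPES = {"uint8", "uint16", "float32", "float64"}


def read_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF volume into an ``(x, y, z)`` float array.

    Returns ``(data, metadata)``; metadata carries any JSON image
    description (e.g. the integer scaling recorded by :func:`write_volume`)
    plus the source dtype.  Integer samples are preserved exactly as reals.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"{path}: ragged pages with shapes {sorted(shapes)}")
        arr = tif.asarray()
        desc = tif.pages[0].description
    if arr.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(f"{path}: unsupported sample format {arr.dtype}")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D TIFF, got shape {arr.shape}")
    meta: dict[str, Any] = {"dtype": arr.dtype.name}
    if desc:
        try:
            meta.update(json.loads(desc))
        except (json.JSONDecodeError, TypeError):
            pass
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    if "scale" in meta and "offset" in meta:
        data = data * meta["scale"] + meta["offset"]
    return data, meta


def write_volume(
    data: np.ndarray,
    path: str | Path,
    dtype: str = "float32",
    extra_metadata: dict | None = None,
) -> None:
    """Write an ``(x, y, z)`` volume as a multi-page TIFF, one page per z.

    Integer dtypes are min–max scaled to the full range, with ``scale`` and
    ``offset`` stored in the image description so that
    :func:`read_volume` restores the original values.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("expected a 3D (x, y, z) volume")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    if dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {dtype!r}")
    meta = dict(extra_metadata or {})
    pages = data.transpose(2, 1, 0)
    if dtype in ("uint8", "uint16"):
        full = float(np.iinfo(dtype).max)
        lo, hi = float(pages.min()), float(pages.max())
        scale = (hi - lo) / full if hi > lo else 1.0
        meta.update({"scale": scale, "offset": lo})
        pages = np.round((pages - lo) / scale if hi > lo else pages - lo)
        pages = pages.astype(dtype)
    else:
        pages = pages.astype(dtype)
    tifffile.imwrite(
        Path(path), pages, photometric="minisblack", description=json.dumps(meta)
    )


def config_to_dict(config: Any) -> dict:
    """Serialize a dataclass config to a JSON-safe dict."""
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, np.ndarray):
            continue  # array-valued fields (e.g. a PSF) travel as TIFF, not JSON
        if isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def config_from_dict(cls: type, payload: dict) -> Any:
    """Instantiate a dataclass config from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**payload)
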