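"""Image container and TIFF I/O.

A :class:`ChannelImage` is a single-channel intensity raster with a
physical pixel size (μm/px) and a channel role.  Images are stored on
disk as single-channel TIFFs (16-bit by default) with the pixel size in
the TIFF resolution tags and, redundantly, in a small JSON sidecar named
``<stem>.json``.

Coordinate convention: pixel centers sit at integer indices, origin at
the top-left, 0-based; physical x = col * pixel_size, y = row * pixel_size
(y increases downward).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

ROLES = ("donor", "acceptor", "structural")


@dataclass
class ChannelImage:
    data: np.ndarray
    pixel_size_um: float
    role: str = "structural"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("ChannelImage requires a nonempty 2D raster")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ChannelImage":
        return replace(self, data=data)


def write_channel(img: ChannelImage, path: str | Path, dtype=np.uint16) -> Path:
    """Write a channel to TIFF (+ JSON sidecar with pixel size and role)."""
    path = Path(path)
    data = img.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
    else:
        data = data.astype(dtype)
    # resolution tags: pixels per centimeter
    px_per_cm = 1e4 / img.pixel_size_um
    tifffile.imwrite(path, data, resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"pixel_size_um": img.pixel_size_um, "role": img.role}, indent=1))
    return path


def read_channel(path: str | Path, role: str | None = None) -> ChannelImage:
    """Read a channel TIFF; pixel size from the sidecar, else TIFF tags."""
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    pixel_size = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = meta.get("pixel_size_um")
        role = role or meta.get("role")
    if pixel_size is None:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None:
                num, den = res.value
                px_per_unit = num / den
                scale = {2: 2.54e4, 3: 1e4}.get(getattr(unit.value, "value", unit.value) if unit else 3, 1e4)
                pixel_size = scale / px_per_unit
    if pixel_size is None:
        raise ValueError(f"no pixel size found for {path}")
    return ChannelImage(data=data, pixel_size_um=float(pixel_size),
                        role=role or "structural")
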