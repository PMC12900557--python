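"""Adhesive-pattern cell shapes rasterised to binary masks.

The emulated micropatterns are 17 x 118 μm rectangles (1:7 aspect ratio)
and 50 μm-diameter circles.  A pixel belongs to the mask when its centre
lies inside the analytic shape, which keeps the mask area within 2% of
the analytic area at the default 0.1 μm/px resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CellShapeSpec:
    kind: str = "rectangle"            # "rectangle" | "circle"
    rect_width_um: float = 17.0
    rect_length_um: float = 118.0
    circle_diameter_um: float = 50.0
    pixel_size_um: float = 0.1
    margin_um: float = 5.0             # background border around the pattern

    def __post_init__(self):
        if self.kind not in ("rectangle", "circle"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        for name in ("rect_width_um", "rect_length_um", "circle_diameter_um",
                     "pixel_size_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.margin_um < 0:
            raise ValueError("margin_um must be >= 0")

    @property
    def analytic_area_um2(self) -> float:
        if self.kind == "rectangle":
            return self.rect_width_um * self.rect_length_um
        return np.pi * (self.circle_diameter_um / 2.0) ** 2


@dataclass
class CellMask:
    """Binary foreground raster plus geometry metadata."""

    mask: np.ndarray                   # bool (H, W)
    pixel_size_um: float
    kind: str
    center_um: tuple[float, float]     # (x, y) of the pattern centre
    long_axis_angle: float             # radians; 0 for the rectangle long axis
    radius_um: float | None = None     # circle only

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um ** 2

    def coords_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates in μm of the foreground pixels."""
        ys, xs = np.nonzero(self.mask)
        return xs * self.pixel_size_um, ys * self.pixel_size_um


def make_cell_mask(spec: CellShapeSpec) -> CellMask:
    """Rasterise the adhesive pattern; mask is centred in the frame."""
    px = spec.pixel_size_um
    if spec.kind == "rectangle":
        w_um = spec.rect_length_um + 2 * spec.margin_um
        h_um = spec.rect_width_um + 2 * spec.margin_um
    else:
        w_um = h_um = spec.circle_diameter_um + 2 * spec.margin_um
    nx = int(round(w_um / px)) + 1
    ny = int(round(h_um / px)) + 1
    cx, cy = (nx - 1) / 2.0 * px, (ny - 1) / 2.0 * px
    x = np.arange(nx) * px - cx
    y = np.arange(ny) * px - cy
    X, Y = np.meshgrid(x, y)
    if spec.kind == "rectangle":
        mask = (np.abs(X) <= spec.rect_length_um / 2.0) & \
               (np.abs(Y) <= spec.rect_width_um / 2.0)
        radius = None
    else:
        radius = spec.circle_diameter_um / 2.0
        mask = X ** 2 + Y ** 2 <= radius ** 2
    return CellMask(mask=mask, pixel_size_um=px, kind=spec.kind,
                    center_um=(cx, cy), long_axis_angle=0.0, radius_um=radius)
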