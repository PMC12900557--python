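"""Cell-on-substrate geometry on a graded rectilinear hexahedral grid.

The rectangular cell is half of a spherically capped cylinder (flat face
down), default total length 120 μm including the caps and radius
12.5 μm; the circular cell is a half-sphere of equal volume (radius
computed at runtime, ≈ 23.6 μm with defaults).  Both rest on a linear
elastic substrate block (default 7.9 kPa, ν = 0.45) whose lateral edges
and bottom are fixed.

The mesh is a tensor-product grid: uniform target spacing inside the
cell bounding box, geometrically graded (ratio 1.4) coarsening toward
the substrate boundary.  Elements are classified cell / substrate / void
by their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VOID, CELL, SUBSTRATE = 0, 1, 2


@dataclass
class GeometrySpec:
    kind: str = "rect"                      # "rect" | "circ"
    cyl_total_length_um: float = 120.0
    cyl_radius_um: float = 12.5
    length_includes_caps: bool = True
    circ_radius_um: float | None = None     # None -> equal-volume radius
    substrate_thickness_um: float = 60.0
    substrate_extent_factor: float = 3.0    # lateral extent / cell footprint
    substrate_E_kPa: float = 7.9
    substrate_nu: float = 0.45
    h_cell_um: float = 4.0                  # target element size in the cell
    h_substrate_um: float = 12.0            # coarsest graded element size
    grade_ratio: float = 1.4

    def __post_init__(self):
        if self.kind not in ("rect", "circ"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        for name in ("cyl_total_length_um", "cyl_radius_um",
                     "substrate_thickness_um", "h_cell_um", "h_substrate_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.substrate_extent_factor < 1.0:
            raise ValueError("substrate extent must cover the cell footprint")

    @property
    def straight_length_um(self) -> float:
        L, r = self.cyl_total_length_um, self.cyl_radius_um
        Ls = L - 2.0 * r if self.length_includes_caps else L
        if Ls <= 0:
            raise ValueError("cap radius exceeds half the total length")
        return Ls

    @property
    def rect_volume_um3(self) -> float:
        """Half spherocylinder: pi r^2 Ls / 2 + (2/3) pi r^3."""
        r = self.cyl_radius_um
        return 0.5 * np.pi * r ** 2 * self.straight_length_um \
            + (2.0 / 3.0) * np.pi * r ** 3

    @property
    def sphere_radius_um(self) -> float:
        """Half-sphere radius of the same volume as the rectangular cell."""
        if self.circ_radius_um is not None:
            return self.circ_radius_um
        return float((1.5 * self.rect_volume_um3 / np.pi) ** (1.0 / 3.0))

    @property
    def cell_volume_um3(self) -> float:
        if self.kind == "rect":
            return self.rect_volume_um3
        R = self.sphere_radius_um
        return (2.0 / 3.0) * np.pi * R ** 3

    def footprint_um(self) -> tuple[float, float]:
        """(x, y) half-extents of the cell-substrate contact area."""
        if self.kind == "rect":
            return (self.straight_length_um / 2.0 + self.cyl_radius_um,
                    self.cyl_radius_um)
        R = self.sphere_radius_um
        return (R, R)

    def inside_cell(self, x, y, z):
        """Vectorised point-in-cell predicate (z >= 0 is the cell side)."""
        x, y, z = np.asarray(x), np.asarray(y), np.asarray(z)
        if self.kind == "circ":
            R = self.sphere_radius_um
            return (z >= 0) & (x ** 2 + y ** 2 + z ** 2 <= R ** 2)
        r, Ls = self.cyl_radius_um, self.straight_length_um
        in_straight = (np.abs(x) <= Ls / 2.0) & (y ** 2 + z ** 2 <= r ** 2)
        xc = np.abs(x) - Ls / 2.0
        in_cap = (xc > 0) & (xc ** 2 + y ** 2 + z ** 2 <= r ** 2)
        return (z >= 0) & (in_straight | in_cap)


def _graded_axis(fine_lo: float, fine_hi: float, h: float, h_max: float,
                 ratio: float, out_lo: float, out_hi: float) -> np.ndarray:
    """Node positions: uniform [fine_lo, fine_hi] at h, graded to out_lo/out_hi."""
    n_fine = max(1, int(round((fine_hi - fine_lo) / h)))
    nodes = list(np.linspace(fine_lo, fine_hi, n_fine + 1))
    # grade outward on the high side
    step = h
    x = fine_hi
    while x < out_hi - 1e-9:
        step = min(step * ratio, h_max, out_hi - x)
        # stretch the final step to land exactly on the boundary
        if out_hi - (x + step) < 0.5 * step:
            step = out_hi - x
        x += step
        nodes.append(x)
    step = h
    x = fine_lo
    pre = []
    while x > out_lo + 1e-9:
        step = min(step * ratio, h_max, x - out_lo)
        if (x - step) - out_lo < 0.5 * step:
            step = x - out_lo
        x -= step
        pre.append(x)
    return np.array(pre[::-1] + nodes)


@dataclass
class HexGrid:
    """Rectilinear grid with per-element domain classification."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    material: np.ndarray      # (nex, ney, nez) int, VOID/CELL/SUBSTRATE
    frac: np.ndarray = None   # material volume fraction per element
    spec: GeometrySpec = None

    @property
    def n_elems(self) -> tuple[int, int, int]:
        return (len(self.x) - 1, len(self.y) - 1, len(self.z) - 1)

    def element_volumes(self) -> np.ndarray:
        dx, dy, dz = np.diff(self.x), np.diff(self.y), np.diff(self.z)
        vol = dx[:, None, None] * dy[None, :, None] * dz[None, None, :]
        return vol * self.frac if self.frac is not None else vol

    def cell_volume_um3(self) -> float:
        return float(self.element_volumes()[self.material == CELL].sum())


def build_geometry(spec: GeometrySpec) -> HexGrid:
    """Mesh the cell + substrate; raises on an invalid spec."""
    fx, fy = spec.footprint_um()
    ext_x = spec.substrate_extent_factor * fx
    ext_y = spec.substrate_extent_factor * fy
    h, hmax, g = spec.h_cell_um, spec.h_substrate_um, spec.grade_ratio
    zc = spec.cyl_radius_um if spec.kind == "rect" else spec.sphere_radius_um

    x = _graded_axis(-fx, fx, h, hmax, g, -ext_x, ext_x)
    y = _graded_axis(-fy, fy, h, hmax, g, -ext_y, ext_y)
    # z: substrate [-T, 0] graded downward, cell [0, zc] uniform
    n_zc = max(2, int(round(zc / h)))
    z_cell = np.linspace(0.0, zc, n_zc + 1)
    z_sub = _graded_axis(0.0, zc, h, hmax, g, -spec.substrate_thickness_um, zc)
    z = np.unique(np.concatenate([z_sub[z_sub < 0], z_cell]))

    cx = 0.5 * (x[:-1] + x[1:])
    cy = 0.5 * (y[:-1] + y[1:])
    cz = 0.5 * (z[:-1] + z[1:])
    CX, CY, CZ = np.meshgrid(cx, cy, cz, indexing="ij")
    material = np.full(CX.shape, VOID, dtype=int)
    material[CZ < 0] = SUBSTRATE
    # partial-volume cell elements: the inside fraction (4^3 midpoint
    # subsamples) scales element stiffness, load and volume, so the
    # voxelised cell tracks the analytic volume even when the radius
    # spans only a few elements
    q = (np.arange(4) + 0.5) / 4.0
    frac = np.zeros(CX.shape)
    dxs, dys, dzs = np.diff(x), np.diff(y), np.diff(z)
    for a in q:
        for b in q:
            for c in q:
                frac += spec.inside_cell(
                    x[:-1][:, None, None] + a * dxs[:, None, None],
                    y[:-1][None, :, None] + b * dys[None, :, None],
                    z[:-1][None, None, :] + c * dzs[None, None, :])
    frac /= 64.0
    frac[CZ < 0] = 0.0
    is_cell = frac >= 0.05
    # drop stray cell fragments not face-connected to the substrate
    from scipy import ndimage as _ndi
    lab, nlab = _ndi.label(is_cell)
    if nlab > 1:
        bottom = set(np.unique(lab[:, :, np.searchsorted(z, 0.0)])) - {0}
        is_cell &= np.isin(lab, sorted(bottom))
    material[is_cell] = CELL
    frac = np.where(is_cell, frac, 0.0)
    frac[material == SUBSTRATE] = 1.0
    grid = HexGrid(x=x, y=y, z=z, material=material, frac=frac, spec=spec)
    if not (material == CELL).any():
        raise ValueError("meshing failure: no cell elements; spec: " + repr(spec))
    return grid
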