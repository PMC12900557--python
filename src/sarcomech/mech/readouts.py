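"""Scalar and map readouts from a converged cell-on-substrate solution.

Three predictions mirror what is measured on images: the volume-averaged
volumetric strain carried by alpha-actinin, the order parameter built
from the Q tensor of first-principal-stress directions, and the
substrate traction / surface displacement maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import FieldSolution, _voigt_stress_to_tensor
from .params import ModelParams
from .tensors import I3


def actinin_volumetric_strain(sol: FieldSolution,
                              params: ModelParams | None = None) -> float:
    """Volume-averaged eps2_kk = sigma_kk / (3 K_alpha) over the cell.

    The cell-average of sigma_kk is evaluated through the mean-stress
    identity <sigma> V = \\oint t (x) x dA: the cell surface is traction
    free except at the substrate interface, so the consistent interface
    tractions determine the average exactly.  This boundary form is far
    less sensitive to the voxelised surface than the raw element average
    (which is available as ``_actinin_strain_element_average``).
    """
    p = params or sol.params
    x = sol.node_xyz[sol.iface_nodes]
    t = -sol.iface_traction            # traction on the cell, kPa
    tr = float(np.sum((t * x).sum(axis=1) * sol.iface_area))
    vol = float(sol.elem_vol[sol.cell].sum())
    return tr / vol / (3.0 * p.K_alpha)


def _actinin_strain_element_average(sol: FieldSolution,
                                    params: ModelParams | None = None) -> float:
    """Element-wise average of sigma_kk/(3 K_alpha); first-order in h."""
    p = params or sol.params
    cell = sol.cell
    skk = sol.stress[cell][:, :3].sum(axis=1)
    return float(np.average(skk / (3.0 * p.K_alpha),
                            weights=sol.elem_vol[cell]))


@dataclass
class OrderParameterResult:
    Q: np.ndarray            # volume-averaged Q tensor (traceless)
    S_sim: float             # largest eigenvalue
    director: np.ndarray     # unit principal direction
    n_degenerate: int        # points with (near-)degenerate principal stress


def stress_order_parameter(sol: FieldSolution,
                           degeneracy_rtol: float = 1e-9) -> OrderParameterResult:
    """Q = <(3 n (x) n - I)/2> with n the first-principal-stress direction.

    Q is volume-averaged over the cell; its largest eigenvalue is the
    predicted order parameter.  Degenerate principal stresses fall back
    on the deterministic eigensolver tie-break and are counted.
    """
    cell = sol.cell
    sig = _voigt_stress_to_tensor(sol.stress[cell])
    w, v = np.linalg.eigh(sig)
    n = v[:, :, 2]                      # largest-eigenvalue direction
    scale = np.abs(w).max(axis=1)
    degen = np.sum((w[:, 2] - w[:, 1]) <= degeneracy_rtol * np.maximum(scale, 1e-300))
    Qs = 0.5 * (3.0 * n[:, :, None] * n[:, None, :] - I3)
    vol = sol.elem_vol[cell]
    Q = np.einsum("e,eij->ij", vol, Qs) / vol.sum()
    lam, vec = np.linalg.eigh(Q)
    return OrderParameterResult(Q=Q, S_sim=float(lam[2]), director=vec[:, 2],
                                n_degenerate=int(degen))


def order_parameter_from_directions(n: np.ndarray) -> float:
    """Largest eigenvalue of the mean Q tensor of unit vectors (N, 3)."""
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n, axis=1, keepdims=True)
    Q = 0.5 * (3.0 * np.einsum("ei,ej->ij", n, n) / len(n) - I3)
    return float(np.linalg.eigvalsh(Q)[2])


@dataclass
class TractionMap:
    x: np.ndarray            # grid coordinates (μm)
    y: np.ndarray
    magnitude_pa: np.ndarray  # (ny, nx) traction magnitude (Pa), 0 off-cell
    tx_pa: np.ndarray
    ty_pa: np.ndarray
    node_xy: np.ndarray      # scattered interface node positions
    node_traction_pa: np.ndarray
    node_displacement_um: np.ndarray


def surface_traction_map(sol: FieldSolution, grid_step_um: float = 2.0) -> TractionMap:
    """In-plane traction (and displacement) map on the substrate top surface.

    Node tractions are the consistent interface forces divided by
    tributary area (converted to Pa); they are resampled to a regular
    grid by nearest-node assignment within the cell footprint.
    """
    nodes = sol.iface_nodes
    xy = sol.node_xyz[nodes, :2]
    t_pa = sol.iface_traction * 1e3    # kPa -> Pa
    disp = sol.u[nodes]

    fx, fy = sol.grid.spec.footprint_um()
    gx = np.arange(-fx, fx + grid_step_um / 2, grid_step_um)
    gy = np.arange(-fy, fy + grid_step_um / 2, grid_step_um)
    GX, GY = np.meshgrid(gx, gy)
    d2 = (GX.ravel()[:, None] - xy[:, 0]) ** 2 + (GY.ravel()[:, None] - xy[:, 1]) ** 2
    nearest = np.argmin(d2, axis=1)
    near_enough = d2[np.arange(len(nearest)), nearest] <= (2 * grid_step_um) ** 2
    tx = np.where(near_enough, t_pa[nearest, 0], 0.0).reshape(GX.shape)
    ty = np.where(near_enough, t_pa[nearest, 1], 0.0).reshape(GX.shape)
    mag = np.hypot(tx, ty)
    return TractionMap(x=gx, y=gy, magnitude_pa=mag, tx_pa=tx, ty_pa=ty,
                       node_xy=xy, node_traction_pa=t_pa,
                       node_displacement_um=disp)
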