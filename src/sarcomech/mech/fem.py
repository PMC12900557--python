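"""Small-strain linear elasticity with active eigenstress on a hex grid.

The cell carries the effective sarcomere material (K_eff, mu_eff) plus
the contractile eigenstress rho_eff_v * I + 2 rho_eff_a * dev(sigma_a);
the substrate is passive linear elastic.  The stress-anisotropy tensor
sigma_a is found by fixed-point iteration: solve elasticity, recompute
sigma_a element-wise from the cell stress, repeat until the relative L2
change drops below tolerance.  The stiffness matrix is constant across
iterations, so the sparse LU factorisation is reused.

Elements are 8-node trilinear hexahedra (boxes) with 2x2x2 Gauss
quadrature; Voigt order xx, yy, zz, yz, xz, xy with engineering shear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .constitutive import anisotropy_tensor_batch, sarcomere_effective
from .geometry import CELL, SUBSTRATE, GeometrySpec, HexGrid, build_geometry
from .params import ModelParams
from .tensors import I3

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
# local node order: index = k*4 + j*2 + i  (i->x, j->y, k->z)
_LOCAL = np.array([[i, j, k] for k in (0, 1) for j in (0, 1) for i in (0, 1)])


def _bmats(dx: float, dy: float, dz: float) -> tuple[np.ndarray, np.ndarray]:
    """B matrices (8 GPs, 6x24) and GP weights*detJ for a box element."""
    det = (dx * dy * dz) / 8.0
    signs = 2.0 * _LOCAL - 1.0  # (8, 3) in {-1, +1}
    Bs = np.zeros((8, 6, 24))
    for g, (gx, gy, gz) in enumerate([(a, b, c) for c in _GP for b in _GP for a in _GP]):
        xi = np.array([gx, gy, gz])
        for a in range(8):
            s = signs[a]
            shp = (1 + s * xi) / 2.0
            dN = np.array([s[0] / 2.0 * shp[1] * shp[2],
                           shp[0] * s[1] / 2.0 * shp[2],
                           shp[0] * shp[1] * s[2] / 2.0])
            dN *= 2.0 / np.array([dx, dy, dz])  # d(xi)/d(x)
            c = 3 * a
            Bs[g, 0, c + 0] = dN[0]
            Bs[g, 1, c + 1] = dN[1]
            Bs[g, 2, c + 2] = dN[2]
            Bs[g, 3, c + 1] = dN[2]; Bs[g, 3, c + 2] = dN[1]
            Bs[g, 4, c + 0] = dN[2]; Bs[g, 4, c + 2] = dN[0]
            Bs[g, 5, c + 0] = dN[1]; Bs[g, 5, c + 1] = dN[0]
    return Bs, np.full(8, det)


def isotropic_C(K: float, mu: float) -> np.ndarray:
    """6x6 stiffness (Voigt, engineering shear) from bulk/shear moduli."""
    lam = K - 2.0 * mu / 3.0
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2.0 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def _voigt_stress_to_tensor(v: np.ndarray) -> np.ndarray:
    """(N, 6) stress Voigt -> (N, 3, 3)."""
    t = np.zeros(v.shape[:-1] + (3, 3))
    t[..., 0, 0] = v[..., 0]; t[..., 1, 1] = v[..., 1]; t[..., 2, 2] = v[..., 2]
    t[..., 1, 2] = t[..., 2, 1] = v[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = v[..., 4]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 5]
    return t


def _dev_voigt(v: np.ndarray) -> np.ndarray:
    out = v.copy()
    m = v[..., :3].mean(axis=-1, keepdims=True)
    out[..., :3] -= m
    return out


@dataclass
class FieldSolution:
    """Converged cell-on-substrate solution (element-wise fields)."""

    grid: HexGrid
    params: ModelParams
    node_xyz: np.ndarray          # (Na, 3) active node coordinates
    u: np.ndarray                 # (Na, 3) displacements (μm)
    elem_ijk: np.ndarray          # (Ne, 3) grid indices of active elements
    elem_mat: np.ndarray          # (Ne,) CELL or SUBSTRATE
    elem_centroid: np.ndarray     # (Ne, 3)
    elem_vol: np.ndarray          # (Ne,)
    strain: np.ndarray            # (Ne, 6) Voigt engineering strain
    stress: np.ndarray            # (Ne, 6) Voigt stress (kPa)
    sigma_a: np.ndarray           # (Ne, 3, 3), zero on substrate elements
    residuals: list = field(default_factory=list)
    smooth_step: bool = False
    # interface traction (cell force on substrate top surface)
    iface_nodes: np.ndarray = None     # (Ni,) indices into active nodes
    iface_traction: np.ndarray = None  # (Ni, 3) kPa
    iface_area: np.ndarray = None      # (Ni,) μm^2

    @property
    def cell(self) -> np.ndarray:
        return self.elem_mat == CELL

    def cell_stress_tensors(self) -> np.ndarray:
        return _voigt_stress_to_tensor(self.stress[self.cell])

    def net_interface_force_ratio(self) -> float:
        """|sum of traction forces| / sum |traction force| over the interface."""
        f = self.iface_traction * self.iface_area[:, None]
        denom = np.linalg.norm(f, axis=1).sum()
        return float(np.linalg.norm(f.sum(axis=0)) / denom) if denom > 0 else 0.0


class ContractilitySolver:
    """Assembles once per (grid, params); supports repeated eigenstress solves."""

    def __init__(self, grid: HexGrid, params: ModelParams):
        self.grid, self.params = grid, params
        dm0 = sarcomere_effective(params)  # sigma_a = 0 reference
        self.C_cell = isotropic_C(dm0.K_eff, dm0.mu_eff)
        E, nu = grid.spec.substrate_E_kPa, grid.spec.substrate_nu
        self.C_sub = isotropic_C(E / (3 * (1 - 2 * nu)), E / (2 * (1 + nu)))
        self._build()

    def _build(self):
        g = self.grid
        nx, ny, nz = len(g.x), len(g.y), len(g.z)
        act = np.argwhere(g.material != 0)
        self.elem_ijk = act
        i, j, k = act.T
        self.elem_mat = g.material[i, j, k]
        self.elem_frac = g.frac[i, j, k] if g.frac is not None else np.ones(len(act))
        dx, dy, dz = np.diff(g.x)[i], np.diff(g.y)[j], np.diff(g.z)[k]
        self.elem_vol = dx * dy * dz * self.elem_frac
        self.elem_centroid = np.column_stack([
            0.5 * (g.x[i] + g.x[i + 1]), 0.5 * (g.y[j] + g.y[j + 1]),
            0.5 * (g.z[k] + g.z[k + 1])])

        # global connectivity (full-grid node ids)
        corners = act[:, None, :] + _LOCAL[None, :, :]
        gid = (corners[..., 0] * ny + corners[..., 1]) * nz + corners[..., 2]
        used = np.unique(gid)
        remap = -np.ones(nx * ny * nz, dtype=int)
        remap[used] = np.arange(len(used))
        self.conn = remap[gid]                      # (Ne, 8) active node ids
        self.n_nodes = len(used)
        ii, jj, kk = np.unravel_index(used, (nx, ny, nz))
        self.node_xyz = np.column_stack([g.x[ii], g.y[jj], g.z[kk]])

        # Dirichlet: substrate bottom and lateral boundary
        xb = (np.isclose(self.node_xyz[:, 2], g.z.min())
              | np.isclose(np.abs(self.node_xyz[:, 0]), g.x.max())
              | np.isclose(np.abs(self.node_xyz[:, 1]), g.y.max()))
        self.fixed_nodes = np.nonzero(xb)[0]
        dof_fixed = np.zeros(self.n_nodes * 3, dtype=bool)
        for d in range(3):
            dof_fixed[self.fixed_nodes * 3 + d] = True
        self.free = np.nonzero(~dof_fixed)[0]
        self.dofmap = -np.ones(self.n_nodes * 3, dtype=int)
        self.dofmap[self.free] = np.arange(len(self.free))

        # group elements by (dx, dy, dz, material) and assemble
        key = np.column_stack([np.round(dx, 9), np.round(dy, 9),
                               np.round(dz, 9), self.elem_mat])
        _, inv = np.unique(key, axis=0, return_inverse=True)
        edofs = (self.conn[:, :, None] * 3 + np.arange(3)).reshape(-1, 24)
        rows, cols, vals = [], [], []
        self.G = np.zeros((len(act), 24, 6))      # load matrices, per element
        self.Bmean = np.zeros((len(act), 6, 24))  # mean strain recovery
        for gi in np.unique(inv):
            sel = np.nonzero(inv == gi)[0]
            e0 = sel[0]
            Bs, w = _bmats(dx[e0], dy[e0], dz[e0])
            C = self.C_cell if self.elem_mat[e0] == CELL else self.C_sub
            ke = sum(w[q] * Bs[q].T @ C @ Bs[q] for q in range(8))
            Ge = sum(w[q] * Bs[q].T for q in range(8))
            Bm = Bs.mean(axis=0)
            # partial-volume scaling: stiffness and load follow the
            # material fraction of boundary elements
            self.G[sel] = Ge[None] * self.elem_frac[sel, None, None]
            self.Bmean[sel] = Bm
            r = np.repeat(edofs[sel], 24, axis=1).ravel()
            c = np.tile(edofs[sel], (1, 24)).ravel()
            rows.append(r); cols.append(c)
            vals.append((np.tile(ke.ravel(), (len(sel), 1))
                         * self.elem_frac[sel, None]).ravel())
        rows = np.concatenate(rows); cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        K = sparse.coo_matrix((vals, (rows, cols)),
                              shape=(self.n_nodes * 3, self.n_nodes * 3)).tocsr()
        Kff = K[self.free][:, self.free].tocsc()
        self.K = K
        self.lu = splu(Kff)
        self.edofs = edofs

    # -- eigenstress helpers -------------------------------------------------

    def _eigenstress_voigt(self, sigma_a: np.ndarray) -> np.ndarray:
        """Per-element eigenstress rho_eff_v I + 2rho_eff_a dev(sigma_a) (Voigt)."""
        p = self.params
        fbK = p.K * (p.beta - 1.0) / (p.beta - p.alpha)
        dm = sarcomere_effective(p)
        sa_kk = np.trace(sigma_a, axis1=1, axis2=2)
        rho_v_bar = p.beta * p.rho0 / (p.beta - p.alpha) \
            + p.alpha_a * sa_kk / (3.0 * (p.beta - p.alpha))
        rho_eff_v = p.K_alpha / (p.K_alpha + fbK) * rho_v_bar
        sv = np.zeros((len(sigma_a), 6))
        sa_dev = sigma_a - sa_kk[:, None, None] / 3.0 * I3
        sv[:, 0] = rho_eff_v + dm.two_rho_eff_a * sa_dev[:, 0, 0]
        sv[:, 1] = rho_eff_v + dm.two_rho_eff_a * sa_dev[:, 1, 1]
        sv[:, 2] = rho_eff_v + dm.two_rho_eff_a * sa_dev[:, 2, 2]
        sv[:, 3] = dm.two_rho_eff_a * sa_dev[:, 1, 2]
        sv[:, 4] = dm.two_rho_eff_a * sa_dev[:, 0, 2]
        sv[:, 5] = dm.two_rho_eff_a * sa_dev[:, 0, 1]
        mask = (self.elem_mat != CELL)
        sv[mask] = 0.0
        return sv

    def _solve_once(self, s_eig: np.ndarray) -> np.ndarray:
        f = np.zeros(self.n_nodes * 3)
        fe = -np.einsum("eij,ej->ei", self.G, s_eig)   # (Ne, 24)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        u = np.zeros(self.n_nodes * 3)
        u[self.free] = self.lu.solve(f[self.free])
        return u

    def _fixed_point_map(self, sigma_a: np.ndarray, smooth: bool):
        """One elasticity solve + sigma_a update; returns (new, u, eps, stress)."""
        s_eig = self._eigenstress_voigt(sigma_a)
        u = self._solve_once(s_eig)
        eps = np.einsum("eij,ej->ei", self.Bmean, u[self.edofs])
        stress = np.where((self.elem_mat == CELL)[:, None],
                          eps @ self.C_cell.T + s_eig, eps @ self.C_sub.T)
        new = anisotropy_tensor_batch(_voigt_stress_to_tensor(stress),
                                      smooth=smooth)
        new[self.elem_mat != CELL] = 0.0
        return new, u, eps, stress, s_eig

    def solve(self, tol: float = 1e-3, max_iter: int = 200,
              smooth: bool = False, anderson_m: int = 5,
              sigma_a0: np.ndarray | None = None) -> FieldSolution:
        """Anderson-accelerated fixed-point loop on sigma_a.

        The relative L2 change of sigma_a must drop below ``tol``.  The
        default tolerance reflects the azimuthally (near-)degenerate
        circular geometry, which carries a near-neutral collective
        rotation mode of the anisotropy directions; scalar readouts are
        insensitive to it (see docs/methods.md).
        """
        ne = len(self.elem_mat)
        x = np.zeros(ne * 9) if sigma_a0 is None else np.asarray(
            sigma_a0, dtype=float).reshape(ne * 9).copy()
        residuals: list[float] = []
        hist_x: list[np.ndarray] = []
        hist_f: list[np.ndarray] = []
        for it in range(1, max_iter + 1):
            new, u, eps, stress, s_eig = self._fixed_point_map(
                x.reshape(ne, 3, 3), smooth)
            g = new.ravel()
            f = g - x
            scale = max(np.linalg.norm(g), np.linalg.norm(x), 1e-12)
            res = float(np.linalg.norm(f) / scale)
            residuals.append(res)
            if res < tol:
                sigma_a = new
                break
            hist_x.append(x.copy())
            hist_f.append(f.copy())
            if len(hist_x) > anderson_m:
                hist_x.pop(0)
                hist_f.pop(0)
            if len(hist_x) > 1:
                dF = np.array([hist_f[i + 1] - hist_f[i]
                               for i in range(len(hist_f) - 1)]).T
                dX = np.array([hist_x[i + 1] - hist_x[i]
                               for i in range(len(hist_x) - 1)]).T
                gam, *_ = np.linalg.lstsq(dF, f, rcond=None)
                x = x + f - (dX + dF) @ gam
            else:
                x = x + f
        else:
            raise RuntimeError(
                f"sigma_a fixed point did not converge in {max_iter} "
                f"iterations; residual history {residuals[-5:]}")

        sol = FieldSolution(
            grid=self.grid, params=self.params,
            node_xyz=self.node_xyz, u=u.reshape(-1, 3),
            elem_ijk=self.elem_ijk, elem_mat=self.elem_mat,
            elem_centroid=self.elem_centroid, elem_vol=self.elem_vol,
            strain=eps, stress=stress, sigma_a=sigma_a,
            residuals=residuals, smooth_step=smooth)
        self._interface_traction(sol, u, s_eig)
        return sol

    def _interface_traction(self, sol: FieldSolution, u: np.ndarray,
                            s_eig: np.ndarray) -> None:
        """Consistent nodal tractions transmitted across z = 0.

        The force the cell applies to the substrate at an interface node
        is minus the cell-side internal nodal force; dividing by the
        tributary interface area gives the traction (kPa).
        """
        g = self.grid
        cell_el = np.nonzero(self.elem_mat == CELL)[0]
        f_int = np.zeros(self.n_nodes * 3)
        for gi in cell_el:
            Bs, w = _bmats(*(np.diff(g.x)[self.elem_ijk[gi, 0]],
                             np.diff(g.y)[self.elem_ijk[gi, 1]],
                             np.diff(g.z)[self.elem_ijk[gi, 2]]))
            sig = self.C_cell @ self.strain_of(gi, u) + s_eig[gi]
            fe = self.elem_frac[gi] * sum(w[q] * Bs[q].T @ sig for q in range(8))
            np.add.at(f_int, self.edofs[gi], fe)
        on_iface = np.isclose(self.node_xyz[:, 2], 0.0)
        area = np.zeros(self.n_nodes)
        bottom = cell_el[self.elem_ijk[cell_el, 2] == np.searchsorted(g.z, 0.0)]
        for gi in bottom:
            i, j, k = self.elem_ijk[gi]
            a = np.diff(g.x)[i] * np.diff(g.y)[j] / 4.0
            for n in self.conn[gi][_LOCAL[:, 2] == 0]:
                area[n] += a
        nodes = np.nonzero(on_iface & (area > 0))[0]
        trac = -f_int.reshape(-1, 3)[nodes] / area[nodes, None]
        sol.iface_nodes = nodes
        sol.iface_traction = trac
        sol.iface_area = area[nodes]

    def strain_of(self, gi: int, u: np.ndarray) -> np.ndarray:
        return self.Bmean[gi] @ u[self.edofs[gi]]


def solve_contractility(grid_or_spec, params: ModelParams, tol: float = 1e-3,
                        max_iter: int = 200, smooth: bool = False) -> FieldSolution:
    """Convenience wrapper: build (if needed), assemble, solve."""
    grid = grid_or_spec if isinstance(grid_or_spec, HexGrid) \
        else build_geometry(grid_or_spec)
    return ContractilitySolver(grid, params).solve(tol=tol, max_iter=max_iter,
                                                   smooth=smooth)
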