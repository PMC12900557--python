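"""Small helpers for symmetric second-order tensors.

All model tensors (stress, strain, contractility, anisotropy) are plain
3x3 symmetric ``numpy`` arrays.  The constitutive relations act separately
on the volumetric part ``(t_kk/3) I`` and the trace-free deviator ``t~``,
so the split/recombine helpers live here.  Voigt 6-vectors (engineering
shear convention) are used only at the FEM boundary.
"""

from __future__ import annotations

import numpy as np

I3 = np.eye(3)

# Voigt ordering: xx, yy, zz, yz, xz, xy
_VOIGT_IDX = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def sym(t: np.ndarray) -> np.ndarray:
    """Symmetrize a 3x3 tensor."""
    t = np.asarray(t, dtype=float)
    return 0.5 * (t + t.T)


def is_symmetric(t: np.ndarray, tol: float = 1e-10) -> bool:
    t = np.asarray(t, dtype=float)
    return t.shape == (3, 3) and bool(np.all(np.abs(t - t.T) <= tol * max(1.0, np.abs(t).max())))


def trace(t: np.ndarray) -> float:
    return float(np.trace(t))


def vol_dev(t: np.ndarray) -> tuple[float, np.ndarray]:
    """Split ``t`` into its trace ``t_kk`` and deviator ``t~``.

    Returns ``(t_kk, t_dev)`` with ``t = (t_kk/3) I + t_dev`` and
    ``tr(t_dev) = 0``.
    """
    t = np.asarray(t, dtype=float)
    tkk = float(np.trace(t))
    return tkk, t - (tkk / 3.0) * I3


def from_vol_dev(tkk: float, tdev: np.ndarray) -> np.ndarray:
    return (tkk / 3.0) * I3 + np.asarray(tdev, dtype=float)


def ddot(a: np.ndarray, b: np.ndarray) -> float:
    """Double contraction a_ij b_ij."""
    return float(np.sum(np.asarray(a) * np.asarray(b)))


def to_voigt(t: np.ndarray, strain: bool = False) -> np.ndarray:
    """3x3 symmetric tensor -> Voigt 6-vector (xx, yy, zz, yz, xz, xy).

    With ``strain=True`` the shear entries carry the engineering factor 2.
    """
    t = np.asarray(t, dtype=float)
    v = np.array([t[i, j] for i, j in _VOIGT_IDX])
    if strain:
        v[3:] *= 2.0
    return v


def from_voigt(v: np.ndarray, strain: bool = False) -> np.ndarray:
    v = np.asarray(v, dtype=float).copy()
    if strain:
        v[3:] /= 2.0
    t = np.zeros((3, 3))
    for k, (i, j) in enumerate(_VOIGT_IDX):
        t[i, j] = v[k]
        t[j, i] = v[k]
    return t


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
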