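"""Chemo-mechanical feedback constitutive model of actomyosin contractility.

The model couples cell contractility (a tensor ``rho``) to stress through
mechanosensitive feedback.  Minimising a chemo-mechanical free energy at
fixed external stress yields linear steady-state stress--strain relations
with feedback-renormalised moduli and an active (eigen)stress.  A third
elastic element in series, representing the z-disk crosslinker
alpha-actinin, turns these into effective sarcomere relations used as the
FEM material law.

Conventions: tension positive; all stresses in kPa.  The renormalised
moduli use the model's nondimensional convention, in which the
renormalisation factor reads ``(beta - 1)``; with the default
``alpha = 1`` this factor cancels and ``K_bar = K``, ``mu_bar = mu``.  The variationally exact
steady state of the free energy (which replaces ``beta - 1`` by
``beta - 1/(3K)``-type factors) is available via :func:`stationary_state`;
the two coincide in units where ``3K = 2mu = 1``.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .tensors import I3, ddot, from_vol_dev, sym, vol_dev


@dataclass
class FeedbackModuli:
    """Feedback-renormalised cytoskeletal moduli (parallel elements only)."""

    K_bar: float          # kPa
    mu_bar: float         # kPa
    rho_v_bar: float      # kPa, includes the sigma_a trace coupling
    two_rho_a_bar: float  # dimensionless anisotropy gain


@dataclass
class DerivedModuli:
    """Series-effective sarcomere moduli (actomyosin + alpha-actinin)."""

    K_bar: float
    mu_bar: float
    rho_v_bar: float
    two_rho_a_bar: float
    K_eff: float
    mu_eff: float
    rho_eff_v: float
    two_rho_eff_a: float


@dataclass
class SarcomereStrainPartition:
    """Strain split between the actomyosin element (1) and alpha-actinin (2)."""

    eps1: np.ndarray
    eps2: np.ndarray


@dataclass
class TensorState:
    """A converged homogeneous state of the model."""

    sigma: np.ndarray
    eps: np.ndarray
    sigma_a: np.ndarray
    rho: np.ndarray | None = None
    iterations: int = 0
    residual: float = 0.0


# ---------------------------------------------------------------------------
# stress anisotropy tensor
# ---------------------------------------------------------------------------

def _step_amplitude(s1: float, s2: float, smooth: bool, width: float) -> float:
    """Unit-step gate of the anisotropy tensor.

    The step is centred at principal-stress ratio 1.  Because the ratio is
    ill-defined across zero, the test used is the sign test
    ``s1 > s2 and s1 > 0`` (anisotropic tension exists); the smooth variant
    replaces the hard step by a logistic in the ratio (or the normalised
    difference when s2 <= 0) for solver continuation.
    """
    if not smooth:
        return 1.0 if (s1 > s2 and s1 > 0.0) else 0.0
    if s1 <= 0.0:
        return 0.0
    scale = max(abs(s1), abs(s2), 1e-300)
    if s2 > 1e-12 * scale:
        x = s1 / s2 - 1.0
    else:
        x = (s1 - s2) / scale
    return float(1.0 / (1.0 + np.exp(-np.clip(x / width, -500, 500))))


def anisotropy_tensor(sigma: np.ndarray, smooth: bool = False,
                      width: float = 0.05) -> np.ndarray:
    """Stress-anisotropy tensor sigma_a = H(s1/s2 - 1) * s1 * (n (x) n).

    ``s1 >= s2 >= s3`` are the principal stresses (tension positive) and
    ``n`` the unit eigenvector of the largest.  Isotropic or compressive
    states give zero.
    """
    sigma = sym(sigma)
    w, v = np.linalg.eigh(sigma)
    s1, s2 = w[2], w[1]
    amp = _step_amplitude(s1, s2, smooth, width) * s1
    if amp == 0.0:
        return np.zeros((3, 3))
    n = v[:, 2]
    return amp * np.outer(n, n)


def anisotropy_tensor_batch(sigma: np.ndarray, smooth: bool = False,
                            width: float = 0.05) -> np.ndarray:
    """Vectorised :func:`anisotropy_tensor` for an (N, 3, 3) stack."""
    sigma = 0.5 * (sigma + np.transpose(sigma, (0, 2, 1)))
    w, v = np.linalg.eigh(sigma)
    s1, s2 = w[:, 2], w[:, 1]
    if smooth:
        scale = np.maximum(np.maximum(np.abs(s1), np.abs(s2)), 1e-300)
        x = np.where(s2 > 1e-12 * scale, s1 / np.where(s2 == 0, 1.0, s2) - 1.0,
                     (s1 - s2) / scale)
        h = 1.0 / (1.0 + np.exp(-np.clip(x / width, -500, 500)))
        h = np.where(s1 > 0.0, h, 0.0)
    else:
        h = ((s1 > s2) & (s1 > 0.0)).astype(float)
    n = v[:, :, 2]
    return (h * s1)[:, None, None] * n[:, :, None] * n[:, None, :]


# ---------------------------------------------------------------------------
# steady-state moduli
# ---------------------------------------------------------------------------

def feedback_moduli(params: ModelParams, sigma_a: np.ndarray | None = None) -> FeedbackModuli:
    """Renormalised moduli of the parallel actomyosin element.

    K_bar = K (beta-1)/(beta-alpha),  mu_bar = mu (beta-1)/(beta-alpha),
    3 rho_v_bar = 3 beta rho0/(beta-alpha) + alpha_a/(beta-alpha) * tr(sigma_a),
    2 rho_a_bar = alpha_a/(beta-alpha).
    """
    p = params
    denom = p.beta - p.alpha
    if denom <= 0:
        raise ValueError("beta must exceed alpha")
    sa_kk = float(np.trace(sigma_a)) if sigma_a is not None else 0.0
    K_bar = p.K * (p.beta - 1.0) / denom
    mu_bar = p.mu * (p.beta - 1.0) / denom
    rho_v_bar = p.beta * p.rho0 / denom + p.alpha_a * sa_kk / (3.0 * denom)
    two_rho_a_bar = p.alpha_a / denom
    return FeedbackModuli(K_bar, mu_bar, rho_v_bar, two_rho_a_bar)


def sarcomere_effective(params: ModelParams, sigma_a: np.ndarray | None = None) -> DerivedModuli:
    """Series combination with the alpha-actinin element.

    K_eff = K_alpha K_bar/(K_alpha + K_bar); the active terms are scaled
    by the stiffness-partition factors K_alpha/(K_alpha + K_bar) and
    mu_alpha/(mu_alpha + mu_bar).
    """
    fb = feedback_moduli(params, sigma_a)
    Ka, mua = params.K_alpha, params.mu_alpha
    K_eff = Ka * fb.K_bar / (Ka + fb.K_bar)
    mu_eff = mua * fb.mu_bar / (mua + fb.mu_bar)
    rho_eff_v = Ka / (Ka + fb.K_bar) * fb.rho_v_bar
    two_rho_eff_a = fb.two_rho_a_bar * mua / (fb.mu_bar + mua)
    return DerivedModuli(fb.K_bar, fb.mu_bar, fb.rho_v_bar, fb.two_rho_a_bar,
                         K_eff, mu_eff, rho_eff_v, two_rho_eff_a)


def total_stress(eps: np.ndarray, sigma_a: np.ndarray, params: ModelParams) -> np.ndarray:
    """Total sarcomere stress: sigma_kk = 3 K_eff eps_kk + 3 rho_eff_v,
    sigma~ = 2 mu_eff eps~ + 2 rho_eff_a sigma_a~."""
    dm = sarcomere_effective(params, sigma_a)
    ekk, edev = vol_dev(sym(eps))
    _, sa_dev = vol_dev(sym(sigma_a))
    skk = 3.0 * dm.K_eff * ekk + 3.0 * dm.rho_eff_v
    sdev = 2.0 * dm.mu_eff * edev + dm.two_rho_eff_a * sa_dev
    return from_vol_dev(skk, sdev)


def invert_total_stress(sigma: np.ndarray, sigma_a: np.ndarray,
                        params: ModelParams) -> np.ndarray:
    """Total strain for a given total stress at fixed sigma_a."""
    dm = sarcomere_effective(params, sigma_a)
    skk, sdev = vol_dev(sym(sigma))
    _, sa_dev = vol_dev(sym(sigma_a))
    ekk = (skk - 3.0 * dm.rho_eff_v) / (3.0 * dm.K_eff)
    edev = (sdev - dm.two_rho_eff_a * sa_dev) / (2.0 * dm.mu_eff)
    return from_vol_dev(ekk, edev)


def partition_strain(sigma: np.ndarray, params: ModelParams,
                     sigma_a: np.ndarray | None = None) -> SarcomereStrainPartition:
    """Split total strain into actomyosin (1) and alpha-actinin (2) parts.

    The crosslinker element carries the full stress:
    eps2_kk = sigma_kk/(3 K_alpha), eps2~ = sigma~/(2 mu_alpha); the
    actomyosin element balances the same stress minus its active part.
    If ``sigma_a`` is not supplied it is recomputed from ``sigma``.
    """
    sigma = sym(sigma)
    if sigma_a is None:
        sigma_a = anisotropy_tensor(sigma)
    fb = feedback_moduli(params, sigma_a)
    skk, sdev = vol_dev(sigma)
    _, sa_dev = vol_dev(sym(sigma_a))
    e2 = from_vol_dev(skk / (3.0 * params.K_alpha), sdev / (2.0 * params.mu_alpha))
    e1_kk = (skk - 3.0 * fb.rho_v_bar) / (3.0 * fb.K_bar)
    e1_dev = (sdev - fb.two_rho_a_bar * sa_dev) / (2.0 * fb.mu_bar)
    e1 = from_vol_dev(e1_kk, e1_dev)
    return SarcomereStrainPartition(eps1=e1, eps2=e2)


# ---------------------------------------------------------------------------
# free energy and its exact stationary state
# ---------------------------------------------------------------------------

def free_energy_density(eps: np.ndarray, rho: np.ndarray, sigma_ext: np.ndarray,
                        sigma_a: np.ndarray, params: ModelParams) -> float:
    """Chemo-mechanical free-energy density U (kPa = kJ/m^3 scale).

    Terms: cytoskeletal strain energy, external work (at fixed external
    stress), motor binding energy, ATP-hydrolysis energy coupled to the
    mechanosensitive feedback, and motor work.
    """
    p = params
    ekk, edev = vol_dev(sym(eps))
    rkk, rdev = vol_dev(sym(rho))
    skk, sdev = vol_dev(sym(sigma_ext))
    sakk, sadev = vol_dev(sym(sigma_a))
    strain_energy = 0.5 * p.K * ekk ** 2 + p.mu * ddot(edev, edev)
    external_work = -(skk * ekk) / 3.0 - ddot(sdev, edev)
    binding = p.beta / 6.0 * (rkk - 3.0 * p.rho0) ** 2 + p.beta / 2.0 * ddot(rdev, rdev)
    atp = -(rkk * (p.alpha * skk + p.alpha_a * sakk)) / 3.0 \
        - ddot(rdev, p.alpha * sdev + p.alpha_a * sadev)
    motor_work = rkk * ekk / 3.0 + ddot(rdev, edev)
    return float(strain_energy + external_work + binding + atp + motor_work)


def stationary_state(params: ModelParams, sigma_ext: np.ndarray,
                     sigma_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact minimiser (eps, rho) of the free energy at fixed external stress.

    Closed-form solution of the simultaneous stationarity conditions
    dU/d(eps) = 0 and dU/d(rho) = 0:

    eps_kk = ((beta - alpha) sigma_kk - alpha_a tr(sigma_a) - 3 beta rho0) / (3 K beta - 1)
    eps~   = ((beta - alpha) sigma~ - alpha_a sigma_a~) / (2 mu beta - 1)
    rho    = recovered from the mechanical balance sigma = 3K eps_vol + ... + rho.
    """
    p = params
    if 3.0 * p.K * p.beta <= 1.0 or 2.0 * p.mu * p.beta <= 1.0:
        raise ValueError("parameters outside the stable range of the energy "
                         "(need 3*K*beta > 1 and 2*mu*beta > 1)")
    skk, sdev = vol_dev(sym(sigma_ext))
    sakk, sadev = vol_dev(sym(sigma_a))
    ekk = ((p.beta - p.alpha) * skk - p.alpha_a * sakk - 3.0 * p.beta * p.rho0) \
        / (3.0 * p.K * p.beta - 1.0)
    edev = ((p.beta - p.alpha) * sdev - p.alpha_a * sadev) / (2.0 * p.mu * p.beta - 1.0)
    rkk = skk - 3.0 * p.K * ekk
    rdev = sdev - 2.0 * p.mu * edev
    return from_vol_dev(ekk, edev), from_vol_dev(rkk, rdev)


# ---------------------------------------------------------------------------
# 0-D self-consistent solver
# ---------------------------------------------------------------------------

def homogeneous_fixed_point(params: ModelParams, loading: str = "traction-free",
                            strain: np.ndarray | None = None, tol: float = 1e-8,
                            max_iter: int = 100, smooth: bool = False) -> TensorState:
    """Self-consistent homogeneous state: iterate sigma_a <- A(sigma(sigma_a)).

    ``loading='traction-free'`` solves sigma_total = 0 for the strain;
    ``loading='strain'`` holds the supplied total strain fixed and solves
    for the stress.  Convergence: relative Frobenius change of sigma_a
    below ``tol``.
    """
    if loading not in ("traction-free", "strain"):
        raise ValueError(f"unknown loading {loading!r}")
    if loading == "strain":
        if strain is None:
            raise ValueError("loading='strain' requires a strain tensor")
        strain = sym(strain)
    sigma_a = np.zeros((3, 3))
    resid = np.inf
    for it in range(1, max_iter + 1):
        if loading == "traction-free":
            sigma = np.zeros((3, 3))
            eps = invert_total_stress(sigma, sigma_a, params)
        else:
            eps = strain
            sigma = total_stress(eps, sigma_a, params)
        sigma_a_new = anisotropy_tensor(sigma, smooth=smooth)
        scale = max(np.linalg.norm(sigma_a_new), np.linalg.norm(sigma_a), 1e-12)
        resid = np.linalg.norm(sigma_a_new - sigma_a) / scale
        sigma_a = sigma_a_new
        if resid < tol:
            rho = stationary_state(params, sigma, sigma_a)[1]
            return TensorState(sigma=sigma, eps=eps, sigma_a=sigma_a, rho=rho,
                               iterations=it, residual=resid)
    raise RuntimeError(
        f"anisotropy fixed point did not converge in {max_iter} iterations "
        f"(last relative residual {resid:.3e})")
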