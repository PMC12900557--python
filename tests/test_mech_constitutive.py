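"""Chemo-mechanical constitutive model: oracles and tensor properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcomech.mech import (CONTRACTED, ModelParams, anisotropy_tensor,
                            feedback_moduli, free_energy_density,
                            homogeneous_fixed_point, invert_total_stress,
                            partition_strain, sarcomere_effective,
                            stationary_state, total_stress)
from sarcomech.mech.tensors import I3, random_rotation, sym, vol_dev

BETA4 = ModelParams(beta=4.0)


def _random_sym(rng, scale=1.0):
    a = rng.normal(size=(3, 3)) * scale
    return sym(a)


# ---------------------------------------------------------------------------
# anisotropy tensor
# ---------------------------------------------------------------------------

def test_isotropic_stress_has_no_anisotropy():
    assert np.allclose(anisotropy_tensor(2.5 * I3), 0.0)
    assert np.allclose(anisotropy_tensor(np.zeros((3, 3))), 0.0)


def test_uniaxial_dominant_stress():
    sa = anisotropy_tensor(np.diag([2.0, 1.0, 1.0]))
    expected = np.zeros((3, 3))
    expected[0, 0] = 2.0
    assert np.allclose(sa, expected)


def test_compressive_states_inactive():
    assert np.allclose(anisotropy_tensor(np.diag([-1.0, -2.0, -3.0])), 0.0)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 10_000))
def test_anisotropy_rotation_equivariance(seed):
    rng = np.random.default_rng(seed)
    sigma = _random_sym(rng, 2.0)
    R = random_rotation(rng)
    lhs = anisotropy_tensor(R @ sigma @ R.T)
    rhs = R @ anisotropy_tensor(sigma) @ R.T
    assert np.allclose(lhs, rhs, atol=1e-10)


# ---------------------------------------------------------------------------
# feedback and effective moduli (renormalised-moduli convention)
# ---------------------------------------------------------------------------

def test_alpha_one_leaves_moduli_unrenormalised():
    fb = feedback_moduli(BETA4)
    assert fb.K_bar == pytest.approx(BETA4.K)
    assert fb.mu_bar == pytest.approx(BETA4.mu)


def test_anisotropy_gain_value():
    assert feedback_moduli(BETA4).two_rho_a_bar == pytest.approx(2.0 / 3.0)


def test_quiescent_volumetric_active_stress():
    assert feedback_moduli(BETA4).rho_v_bar == pytest.approx(8.0 / 3.0)


def test_series_effective_moduli():
    dm = sarcomere_effective(BETA4)
    assert dm.K_eff == pytest.approx(BETA4.K / 2.0)      # K_alpha = K_bar
    assert dm.K_eff == pytest.approx(1.6665, abs=1e-4)
    assert dm.two_rho_eff_a == pytest.approx(1.0 / 3.0)  # (2/3) * 1/2


def test_rigid_crosslinker_limit():
    stiff = BETA4.replace(K_alpha=1e6 * BETA4.K, mu_alpha=1e6 * BETA4.mu)
    dm = sarcomere_effective(stiff)
    fb = feedback_moduli(stiff)
    assert dm.K_eff == pytest.approx(fb.K_bar, rel=1e-4)
    assert dm.rho_eff_v == pytest.approx(fb.rho_v_bar, rel=1e-4)


def test_effective_moduli_bounded_by_components():
    dm = sarcomere_effective(BETA4)
    assert dm.K_eff < min(dm.K_bar, BETA4.K_alpha)
    assert dm.mu_eff < min(dm.mu_bar, BETA4.mu_alpha)


def test_monotonicity_in_activity_parameters():
    rho_effs = [sarcomere_effective(BETA4.replace(rho0=r)).rho_eff_v
                for r in (0.5, 1.0, 2.0, 4.0)]
    assert all(a < b for a, b in zip(rho_effs, rho_effs[1:]))
    gains = [sarcomere_effective(BETA4.replace(alpha_a=a)).two_rho_eff_a
             for a in (0.5, 1.0, 2.0, 2.5)]
    assert all(a < b for a, b in zip(gains, gains[1:]))


def test_parameter_guards():
    with pytest.raises(ValueError):
        ModelParams(beta=0.5)                 # beta <= alpha
    with pytest.raises(ValueError):
        ModelParams(beta=2.0, alpha_a=2.0)    # gain >= 1
    with pytest.raises(ValueError):
        ModelParams(K=-1.0)


# ---------------------------------------------------------------------------
# total stress / strain partition
# ---------------------------------------------------------------------------

def test_zero_strain_gives_isotropic_prestress():
    sigma = total_stress(np.zeros((3, 3)), np.zeros((3, 3)), BETA4)
    dm = sarcomere_effective(BETA4)
    assert np.allclose(sigma, dm.rho_eff_v * I3)


def test_superposition_at_fixed_anisotropy(rng):
    e1, e2 = _random_sym(rng, 0.1), _random_sym(rng, 0.1)
    sa = anisotropy_tensor(np.diag([1.5, 1.0, 0.5]))
    lhs = total_stress(e1 + e2, sa, BETA4)
    rhs = (total_stress(e1, sa, BETA4) + total_stress(e2, sa, BETA4)
           - total_stress(np.zeros((3, 3)), sa, BETA4))
    assert np.allclose(lhs, rhs, atol=1e-12)


def test_unloaded_crosslinker_carries_no_strain():
    part = partition_strain(np.zeros((3, 3)), BETA4, np.zeros((3, 3)))
    assert np.allclose(part.eps2, 0.0)


def test_isotropic_stress_partition():
    p = 1.2
    part = partition_strain(p * I3, BETA4, np.zeros((3, 3)))
    assert np.allclose(part.eps2, p / (3.0 * BETA4.K_alpha) * I3)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.integers(0, 10_000))
def test_series_elimination_oracle(seed):
    """Three-element relations: eps1 + eps2 equals the strain recovered
    by inverting the effective law, to 1e-10 relative."""
    rng = np.random.default_rng(seed)
    sigma = _random_sym(rng, 2.0)
    sa = anisotropy_tensor(sigma)
    part = partition_strain(sigma, BETA4, sa)
    eps_total = invert_total_stress(sigma, sa, BETA4)
    scale = max(np.abs(eps_total).max(), 1.0)
    assert np.allclose(part.eps1 + part.eps2, eps_total, atol=1e-10 * scale)


# ---------------------------------------------------------------------------
# free energy: quiescent reference and stationarity oracle
# ---------------------------------------------------------------------------

def test_quiescent_reference_energy_is_zero():
    rho = BETA4.rho0 * I3
    U = free_energy_density(np.zeros((3, 3)), rho, np.zeros((3, 3)),
                            np.zeros((3, 3)), BETA4)
    assert U == pytest.approx(0.0, abs=1e-14)


def _fd_gradients(eps, rho, sig, sa, params, h=1e-6):
    """Finite-difference gradients of U wrt eps and rho (symmetric pairs)."""
    g_eps = np.zeros((3, 3))
    g_rho = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            de = np.zeros((3, 3)); de[i, j] = de[j, i] = h
            g_eps[i, j] = (free_energy_density(eps + de, rho, sig, sa, params)
                           - free_energy_density(eps - de, rho, sig, sa, params)) / (2 * h)
            g_rho[i, j] = (free_energy_density(eps, rho + de, sig, sa, params)
                           - free_energy_density(eps, rho - de, sig, sa, params)) / (2 * h)
    return g_eps, g_rho


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_steady_state_is_stationary_point(seed):
    """Minimising the free energy reproduces the steady-state relations:
    finite-difference gradients vanish at the closed-form minimiser."""
    rng = np.random.default_rng(seed)
    sigma_ext = _random_sym(rng, 1.5)
    sa = anisotropy_tensor(_random_sym(rng, 2.0))
    eps, rho = stationary_state(BETA4, sigma_ext, sa)
    g_eps, g_rho = _fd_gradients(eps, rho, sigma_ext, sa, BETA4)
    scale = abs(free_energy_density(eps * 0, rho * 0 + BETA4.rho0 * I3 * 0,
                                    sigma_ext, sa, BETA4)) + 1.0
    assert np.abs(g_eps).max() < 1e-6 * scale
    assert np.abs(g_rho).max() < 1e-6 * scale


def test_renormalised_moduli_are_stationarity_in_normalised_units():
    """In units where 3K = 2mu = 1 the conventional renormalised moduli equal
    the variationally exact ones."""
    p = ModelParams(K=1.0 / 3.0, mu=0.5, beta=4.0)
    fb = feedback_moduli(p)
    denom = p.beta - p.alpha
    assert fb.K_bar == pytest.approx((3 * p.K * p.beta - 1) / (3 * denom))
    assert fb.mu_bar == pytest.approx((2 * p.mu * p.beta - 1) / (2 * denom))


# ---------------------------------------------------------------------------
# homogeneous fixed point
# ---------------------------------------------------------------------------

def test_traction_free_closed_form():
    state = homogeneous_fixed_point(BETA4, "traction-free")
    assert state.iterations == 1
    assert np.allclose(state.sigma, 0.0)
    assert np.allclose(state.sigma_a, 0.0)
    dm = sarcomere_effective(BETA4)
    ekk = np.trace(state.eps)
    assert ekk == pytest.approx(-dm.rho_eff_v / dm.K_eff)
    assert ekk == pytest.approx(-0.800, abs=1e-3)
    assert ekk < 0  # contraction


def test_prescribed_uniaxial_strain_aligns_anisotropy():
    eps = np.diag([0.1, 0.0, 0.0])
    state = homogeneous_fixed_point(BETA4, "strain", strain=eps)
    w, v = np.linalg.eigh(state.sigma_a)
    n = v[:, 2]
    assert abs(n[0]) > 0.999
    assert w[2] > 0


def test_feedback_off_recovers_passive_elasticity():
    passive = ModelParams(alpha=0.0, alpha_a=0.0, rho0=0.0, beta=4.0)
    eps = np.diag([0.05, -0.02, 0.01])
    state = homogeneous_fixed_point(passive, "strain", strain=eps)
    dm = sarcomere_effective(passive)
    ekk, edev = vol_dev(eps)
    expected = dm.K_eff * ekk * I3 + 2.0 * dm.mu_eff * edev
    assert np.allclose(state.sigma, expected, atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_frame_indifference_of_constitutive_chain(seed):
    """total_stress commutes with rigid rotations."""
    rng = np.random.default_rng(seed)
    eps = _random_sym(rng, 0.2)
    sa = anisotropy_tensor(_random_sym(rng, 1.0))
    R = random_rotation(rng)
    lhs = total_stress(R @ eps @ R.T, R @ sa @ R.T, BETA4)
    rhs = R @ total_stress(eps, sa, BETA4) @ R.T
    assert np.allclose(lhs, rhs, atol=1e-10)


def test_vol_dev_orthogonality_preserved(rng):
    t = _random_sym(rng, 3.0)
    tkk, tdev = vol_dev(t)
    assert np.trace(tdev) == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(tkk / 3.0 * I3 + tdev, t)
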