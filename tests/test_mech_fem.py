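"""Cell-on-substrate FEM: geometry, solver checks on reduced meshes."""

import numpy as np
import pytest

from sarcomech.mech import ModelParams
from sarcomech.mech.fem import ContractilitySolver, solve_contractility
from sarcomech.mech.geometry import CELL, GeometrySpec, build_geometry
from sarcomech.mech.readouts import (actinin_volumetric_strain,
                                     order_parameter_from_directions,
                                     stress_order_parameter,
                                     surface_traction_map)

# reduced geometry keeps unit tests fast; physics identical
SMALL_RECT = dict(kind="rect", cyl_total_length_um=60.0, cyl_radius_um=8.0,
                  substrate_thickness_um=30.0, h_cell_um=4.0)
CONTR = ModelParams()


def test_capped_half_cylinder_volume_oracle():
    spec = GeometrySpec(kind="rect")
    r, Ls = 12.5, 120.0 - 2 * 12.5
    analytic = 0.5 * np.pi * r ** 2 * Ls + (2.0 / 3.0) * np.pi * r ** 3
    assert spec.rect_volume_um3 == pytest.approx(analytic)
    grid = build_geometry(spec)
    assert abs(grid.cell_volume_um3() - analytic) / analytic < 0.02


def test_equal_volume_half_sphere():
    spec = GeometrySpec(kind="circ")
    assert spec.sphere_radius_um == pytest.approx(23.6, abs=0.1)
    grid = build_geometry(spec)
    assert abs(grid.cell_volume_um3() - spec.rect_volume_um3) \
        / spec.rect_volume_um3 < 0.02


def test_substrate_must_cover_footprint():
    with pytest.raises(ValueError):
        GeometrySpec(substrate_extent_factor=0.8)


def test_passive_unloaded_cell_does_not_move():
    passive = ModelParams(alpha=0.0, alpha_a=0.0, rho0=0.0)
    sol = solve_contractility(GeometrySpec(**SMALL_RECT), passive)
    assert np.abs(sol.u).max() < 1e-9
    assert actinin_volumetric_strain(sol) == pytest.approx(0.0, abs=1e-12)
    tmap = surface_traction_map(sol)
    assert np.abs(tmap.magnitude_pa).max() < 1e-6


def test_displacement_linear_in_rho0_without_feedback():
    spec = GeometrySpec(**SMALL_RECT)
    grid = build_geometry(spec)
    umax = []
    rhos = [0.5, 1.0, 2.0]
    for r in rhos:
        params = ModelParams(alpha=0.0, alpha_a=0.0, rho0=r)
        sol = ContractilitySolver(grid, params).solve()
        umax.append(np.abs(sol.u).max())
    fit = np.polyfit(rhos, umax, 1)
    pred = np.polyval(fit, rhos)
    ss_res = np.sum((np.array(umax) - pred) ** 2)
    ss_tot = np.sum((np.array(umax) - np.mean(umax)) ** 2)
    assert 1.0 - ss_res / ss_tot > 0.999


def test_halving_crosslinker_modulus_doubles_its_strain():
    sol = solve_contractility(GeometrySpec(**SMALL_RECT), CONTR)
    e2 = actinin_volumetric_strain(sol)
    e2_half = actinin_volumetric_strain(sol, CONTR.replace(K_alpha=CONTR.K_alpha / 2))
    assert e2_half == pytest.approx(2.0 * e2)


def test_mesh_refinement_stability():
    """Halving the element size moves the scalar readouts by < 5%."""
    tiny = dict(kind="rect", cyl_total_length_um=40.0, cyl_radius_um=6.0,
                substrate_thickness_um=24.0)
    coarse = solve_contractility(GeometrySpec(**tiny, h_cell_um=2.0), CONTR)
    fine = solve_contractility(GeometrySpec(**tiny, h_cell_um=1.0), CONTR)
    S_c = stress_order_parameter(coarse).S_sim
    S_f = stress_order_parameter(fine).S_sim
    e_c = actinin_volumetric_strain(coarse)
    e_f = actinin_volumetric_strain(fine)
    assert abs(S_f - S_c) / abs(S_f) < 0.05
    assert abs(e_f - e_c) / abs(e_f) < 0.05


def test_converged_state_independent_of_initialisation():
    spec = GeometrySpec(**SMALL_RECT)
    grid = build_geometry(spec)
    solver = ContractilitySolver(grid, CONTR)
    a = solver.solve()
    x0 = np.zeros((len(solver.elem_mat), 3, 3))
    x0[solver.elem_mat == CELL] = np.diag([1.0, 0.0, 0.0])
    b = solver.solve(sigma_a0=x0)
    scale = np.linalg.norm(a.sigma_a)
    assert np.linalg.norm(a.sigma_a - b.sigma_a) / scale < 5e-3
    assert stress_order_parameter(a).S_sim == pytest.approx(
        stress_order_parameter(b).S_sim, abs=1e-3)


def test_interface_force_balance():
    sol = solve_contractility(GeometrySpec(**SMALL_RECT), CONTR)
    assert sol.net_interface_force_ratio() < 0.01


def test_synthetic_direction_fields_order_parameter(rng):
    """Q-tensor limits: perfect alignment -> 1; 3D isotropy -> 0."""
    aligned = np.tile([1.0, 0.0, 0.0], (100, 1))
    assert order_parameter_from_directions(aligned) == pytest.approx(1.0)
    v = rng.standard_normal((100_000, 3))
    assert abs(order_parameter_from_directions(v)) < 0.02


def test_degenerate_principal_stress_counted():
    sol = solve_contractility(GeometrySpec(**SMALL_RECT),
                              ModelParams(alpha=0.0, alpha_a=0.0, rho0=0.0))
    res = stress_order_parameter(sol)
    # unloaded: every cell element is exactly degenerate (zero stress)
    assert res.n_degenerate == int(sol.cell.sum())
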