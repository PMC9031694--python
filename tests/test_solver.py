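"""Field solver against closed-form oracles and conservation laws."""

import numpy as np
import pytest

import pfasim as pf
from pfasim.config import LABEL_MYOCARDIUM, electrode_label
from pfasim.solver import (
    SolverError,
    assemble_conduction_system,
    solve_potential,
)

from conftest import (
    concentric_cylinder_phantom,
    custom_phantom,
    parallel_plate_phantom,
    uniform_grid,
)


@pytest.fixture(scope="module")
def plate_solution():
    phantom, d = parallel_plate_phantom(h=0.25)
    bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=90.0)
    system = assemble_conduction_system(phantom, bc)
    return solve_potential(system), phantom, d


def test_parallel_plate_uniform_field(plate_solution):
    """|E| = V/d everywhere between the plates, within 0.5%."""
    sol, phantom, d = plate_solution
    myo = phantom.label_grid == LABEL_MYOCARDIUM
    expected = 90.0 / d * 10.0  # V/cm
    values = sol.magnitude[myo]
    assert np.all(np.abs(values - expected) / expected < 0.005)


def test_parallel_plate_vectors_along_normal(plate_solution):
    sol, phantom, _ = plate_solution
    myo = phantom.label_grid == LABEL_MYOCARDIUM
    E = pf.compute_field_vectors(sol)
    ez = np.abs(E[2][myo])
    et = np.hypot(E[0][myo], E[1][myo])
    angles = np.degrees(np.arctan2(et, ez))
    assert np.all(angles < 1.0)


def test_parallel_plate_above_ire_threshold():
    """90 V across a 1 mm tissue gap: 900 V/cm, over the 400 V/cm level."""
    phantom, d = parallel_plate_phantom(h=0.25, gap=1.5)
    bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=90.0)
    sol = solve_potential(assemble_conduction_system(phantom, bc))
    myo = phantom.label_grid == LABEL_MYOCARDIUM
    assert np.all(sol.magnitude[myo] >= 400.0)


def test_null_excitation_gives_zero_field():
    phantom, _ = parallel_plate_phantom(h=0.5)
    bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=0.0)
    sol = solve_potential(assemble_conduction_system(phantom, bc))
    assert np.all(sol.phi == 0.0)
    assert np.all(sol.magnitude == 0.0)


def test_linearity_in_applied_potential():
    phantom, _ = parallel_plate_phantom(h=0.5)
    sols = []
    for v in (90.0, 180.0):
        bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=v)
        sols.append(solve_potential(assemble_conduction_system(phantom, bc)))
    assert np.allclose(sols[1].phi, 2.0 * sols[0].phi, rtol=1e-6, atol=1e-6)
    assert np.allclose(sols[1].magnitude, 2.0 * sols[0].magnitude, rtol=1e-6, atol=1e-6)


def test_concentric_cylinders_match_log_profile():
    """|E|(r) = V / (r ln(b/a)) within 2% at 0.25 mm voxels (radially
    averaged between the electrodes, away from the rasterised rims)."""
    a, b, V = 3.0, 8.0, 100.0
    phantom = concentric_cylinder_phantom(h=0.25, a=a, b=b)
    bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=V)
    sol = solve_potential(assemble_conduction_system(phantom, bc))
    grid = phantom.grid
    r2d = grid.radius_xy
    kz = grid.shape[2] // 2
    myo = phantom.label_grid[:, :, kz] == LABEL_MYOCARDIUM
    mags = sol.magnitude[:, :, kz]
    for r_lo in np.arange(4.0, 7.0, 0.5):
        sel = myo & (r2d >= r_lo) & (r2d < r_lo + 0.5)
        r_mean = r2d[sel].mean()
        expected = V / (r_mean * np.log(b / a)) * 10.0
        measured = mags[sel].mean()
        assert measured == pytest.approx(expected, rel=0.02)


def test_discrete_maximum_principle(mode_a_coarse, mode_b_coarse):
    for res in (mode_a_coarse, mode_b_coarse):
        sol = res.solutions[0]
        v0 = res.mode.steps[0].applied_potential
        assert sol.phi.min() >= -1e-9
        assert sol.phi.max() <= v0 + 1e-9


def test_current_conservation(mode_a_coarse, mode_b_coarse):
    for res in (mode_a_coarse, mode_b_coarse):
        cur = res.solutions[0].currents
        assert cur["positive"] > 0
        assert cur["ground"] == pytest.approx(cur["positive"], rel=0.01)


def test_mode_a_interspline_cancellation(mode_a_coarse):
    """Between adjacent petals the facing electrodes share polarity, so
    the surface field midway between them collapses well below the
    on-petal maximum — the mechanism behind mode A's lesion gaps."""
    res = mode_a_coarse
    sol = res.solutions[0]
    layout = res.phantom.layout
    e_iv_s1 = layout.electrode(4).center   # iv of spline 1
    e_i_s2 = layout.electrode(5).center    # i of spline 2
    mid = 0.5 * (e_iv_s1 + e_i_s2)
    grid = res.phantom.grid
    i = int(np.argmin(np.abs(grid.x_centers - mid[0])))
    j = int(np.argmin(np.abs(grid.y_centers - mid[1])))
    k_surf = grid.z_layer_index(-0.26)
    myo = res.phantom.myocardium_mask
    spline_max = sol.magnitude[:, :, k_surf][myo[:, :, k_surf]].max()
    mid_field = sol.magnitude[i, j, k_surf]
    assert mid_field < 0.10 * spline_max


def test_antisymmetric_two_electrode_field():
    """Mirror-symmetric electrode pair: phi(x) + phi(mirror x) = V0."""
    grid = uniform_grid(0.25, (0, 8), (0, 4), (0, 4))
    labels = np.full(grid.shape, LABEL_MYOCARDIUM, dtype=np.int16)
    labels[:3, :, :] = electrode_label(1)
    labels[-3:, :, :] = electrode_label(2)
    phantom = custom_phantom(grid, labels)
    bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=100.0)
    sol = solve_potential(assemble_conduction_system(phantom, bc))
    mirrored = sol.phi[::-1, :, :]
    assert np.allclose(sol.phi + mirrored, 100.0, atol=1e-4)
    assert np.allclose(sol.magnitude, sol.magnitude[::-1, :, :], atol=1e-6)


def test_floating_electrode_is_equipotential_and_passive():
    """An undriven electrode between the plates stays equipotential and
    does not source or sink net current."""
    phantom, d = parallel_plate_phantom(h=0.25, gap=10.0)
    labels = phantom.label_grid.copy()
    nz = labels.shape[2]
    labels[6:10, 6:10, nz // 2 - 2 : nz // 2 + 2] = electrode_label(3)
    phantom = custom_phantom(phantom.grid, labels)
    bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=90.0)
    sol = solve_potential(
        assemble_conduction_system(phantom, bc, float_conductors=True)
    )
    vals = sol.phi[labels == electrode_label(3)]
    assert np.ptp(vals) < 1e-9
    assert sol.currents["ground"] == pytest.approx(sol.currents["positive"], rel=0.01)


def test_admittivity_variant_close_to_conduction():
    """At 5 kHz the displacement term shifts myocardial |E| by < 30%
    (in fact by a few percent), justifying the pure-conduction model."""
    phantom, d = parallel_plate_phantom(h=0.5)
    bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=90.0)
    sol_real = solve_potential(assemble_conduction_system(phantom, bc))
    sol_cplx = solve_potential(assemble_conduction_system(phantom, bc, admittivity=True))
    myo = phantom.label_grid == LABEL_MYOCARDIUM
    ratio = sol_cplx.magnitude[myo] / sol_real.magnitude[myo]
    assert np.all(np.abs(ratio - 1.0) < 0.30)


def test_unknown_electrode_in_bc_raises(coarse_phantom):
    bc = pf.BoundarySpec(positive={21}, ground={1}, applied_potential=10.0)
    with pytest.raises(ValueError):
        assemble_conduction_system(coarse_phantom, bc)


def test_nonconvergence_raises():
    phantom, _ = parallel_plate_phantom(h=0.25)
    bc = pf.BoundarySpec(positive={1}, ground={2}, applied_potential=90.0)
    system = assemble_conduction_system(phantom, bc)
    with pytest.raises(SolverError):
        solve_potential(system, tol=1e-12, maxiter=2)


def test_probe_line_returns_depth_profile(mode_b_coarse):
    sol = mode_b_coarse.solutions[0]
    e = mode_b_coarse.phantom.layout.electrode(2)
    profile = pf.probe_line(sol, e.center[0], e.center[1])
    assert profile.shape[1] == 2
    z, mag = profile[:, 0], profile[:, 1]
    in_myo = (z > -10) & (z < 0)
    assert mag[in_myo].max() > 400.0
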