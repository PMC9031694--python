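"""Lesion metrics against constructed analytic shapes.

Annuli, plugs and slit annuli have closed-form widths, depths and
closure properties; the metric code must reproduce them to within one
voxel.
"""

import numpy as np
import pytest

import pfasim as pf
from pfasim.lesion import (
    max_continuous_circumferential_depth,
    max_lesion_depth,
    max_surface_width,
    lesion_report,
    ring_closed,
)

from conftest import annulus_mask_stack, uniform_grid

H = 0.25


def empty_like(ela: pf.ELAMask) -> pf.ELAMask:
    import dataclasses

    return dataclasses.replace(ela, mask=np.zeros_like(ela.mask))


@pytest.fixture(scope="module")
def annulus():
    return annulus_mask_stack(h=H)


def test_single_voxel_depth():
    grid = uniform_grid(0.2, (-2, 2), (-2, 2), (-10, 0))
    mask = np.zeros(grid.shape, dtype=bool)
    k = int(np.argmin(np.abs(grid.z_centers - (-6.1))))
    assert grid.z_centers[k] == pytest.approx(-6.1, abs=1e-9)
    mask[5, 5, k] = True
    ela = pf.ELAMask(
        mask=mask, grid=grid, vein_radius=0.5, reporting_radius=1.8,
        myocardium_thickness=10.0,
    )
    assert max_lesion_depth(ela) == pytest.approx(6.1, abs=1e-9)


def test_empty_mask_zero_report(annulus):
    ela = empty_like(annulus)
    rep = lesion_report(ela)
    assert rep.max_depth == 0.0
    assert rep.max_surface_width == 0.0
    assert rep.max_continuous_circumferential_depth == 0.0
    assert not rep.surface_ring_closed
    assert rep.n_voxels == 0


def test_hemisphere_depth():
    grid = uniform_grid(H, (-8, 8), (-8, 8), (-10, 0))
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    mask = np.zeros(grid.shape, dtype=bool)
    for k, z in enumerate(grid.z_centers):
        mask[:, :, k] = X**2 + Y**2 + z**2 <= 25.0
    ela = pf.ELAMask(
        mask=mask, grid=grid, vein_radius=1.0, reporting_radius=7.0,
        myocardium_thickness=10.0,
    )
    assert max_lesion_depth(ela) == pytest.approx(5.0, abs=H)


def test_annulus_width(annulus):
    assert max_surface_width(annulus) == pytest.approx(11.0, abs=2 * H)


def test_full_disk_width_bounded_by_geometry():
    # lesion covering the whole annular myocardium (vein rim 12.5 mm,
    # reporting cut 25 mm): width is bounded by the annulus itself
    ela = annulus_mask_stack(h=H, r_in=12.5, r_out=40.0, reporting_radius=25.0)
    assert max_surface_width(ela) == pytest.approx(12.5, abs=2 * H)


def test_single_voxel_surface_width():
    grid = uniform_grid(H, (-28, 28), (-28, 28), (-10, 0))
    mask = np.zeros(grid.shape, dtype=bool)
    i = int(np.argmin(np.abs(grid.x_centers - 18.0)))
    j = int(np.argmin(np.abs(grid.y_centers)))
    mask[i, j, -1] = True
    ela = pf.ELAMask(
        mask=mask, grid=grid, vein_radius=12.5, reporting_radius=26.0,
        myocardium_thickness=10.0,
    )
    assert max_surface_width(ela) == pytest.approx(H, abs=1e-6)


def test_annulus_ring_closed_no_gaps(annulus):
    closed, gaps = ring_closed(annulus, 0.0)
    assert closed
    assert gaps == []


def test_slit_annulus_open_with_gap_at_slit():
    ela = annulus_mask_stack(h=H)
    X, Y = np.meshgrid(ela.grid.x_centers, ela.grid.y_centers, indexing="ij")
    theta = np.degrees(np.arctan2(Y, X)) % 360.0
    slit = (theta >= 40.0) & (theta < 42.0)
    import dataclasses

    cut = dataclasses.replace(ela, mask=ela.mask & ~slit[:, :, None])
    closed, gaps = ring_closed(cut, 0.0)
    assert not closed
    assert len(gaps) == 1
    lo, hi = gaps[0]
    assert lo <= 41.0 <= hi


def test_one_voxel_slit_still_detected_as_open():
    """A single-voxel-wide radial cut must open the ring (8-connected
    background leaks through it) and report a gap containing its angle."""
    ela = annulus_mask_stack(h=H)
    import dataclasses

    mask = ela.mask.copy()
    j = int(np.argmin(np.abs(ela.grid.y_centers)))
    mask[ela.grid.x_centers > 0, j, :] = False  # one-row slit along +x
    cut = dataclasses.replace(ela, mask=mask)
    closed, gaps = ring_closed(cut, 0.0)
    assert not closed
    assert any(lo <= 0.0 <= hi or lo <= 360.0 <= hi or (lo - 360.0) <= 0.0 <= (hi - 360.0)
               for lo, hi in gaps)


def test_plug_continuous_depth():
    ela = annulus_mask_stack(h=H, depth=2.7)
    assert max_continuous_circumferential_depth(ela) == pytest.approx(2.7, abs=2 * H)
    assert max_lesion_depth(ela) == pytest.approx(2.7, abs=2 * H)


def test_closed_below_but_open_surface_counts_zero():
    base = annulus_mask_stack(h=H)
    mask = np.zeros_like(base.mask)
    for k, z in enumerate(base.grid.z_centers):
        if 2.0 <= -z <= 3.0:
            mask[:, :, k] = base.mask[:, :, k]
    import dataclasses

    ela = dataclasses.replace(base, mask=mask)
    assert max_continuous_circumferential_depth(ela) == 0.0
    assert max_continuous_circumferential_depth(ela, convention="deepest_closed") == (
        pytest.approx(3.0, abs=2 * H)
    )


def test_transmural_annulus_reaches_wall_thickness(annulus):
    assert max_continuous_circumferential_depth(annulus) == pytest.approx(10.0, abs=H)
    assert max_lesion_depth(annulus) == pytest.approx(10.0, abs=H)


def test_metrics_monotone_under_union(annulus):
    import dataclasses

    rng = np.random.default_rng(7)
    extra = rng.random(annulus.mask.shape) < 0.002
    bigger = dataclasses.replace(annulus, mask=annulus.mask | extra)
    small = annulus_mask_stack(h=H, depth=1.5)
    grown = dataclasses.replace(small, mask=small.mask | (annulus.mask & (annulus.grid.radius_xy < 20)[:, :, None]))
    for a, b in ((annulus, bigger), (small, grown)):
        assert max_lesion_depth(b) >= max_lesion_depth(a)
        assert max_surface_width(b) >= max_surface_width(a)
        assert max_continuous_circumferential_depth(b) >= (
            max_continuous_circumferential_depth(a)
        )


def test_metrics_rotation_invariant_within_voxel():
    import dataclasses

    def slit_at(angle):
        ela = annulus_mask_stack(h=H, depth=4.0)
        X, Y = np.meshgrid(ela.grid.x_centers, ela.grid.y_centers, indexing="ij")
        theta = np.degrees(np.arctan2(Y, X)) % 360.0
        slit = (theta >= angle) & (theta < angle + 3.0)
        return dataclasses.replace(ela, mask=ela.mask & ~slit[:, :, None])

    a, b = slit_at(10.0), slit_at(130.0)
    assert max_surface_width(a) == pytest.approx(max_surface_width(b), abs=2 * H)
    assert max_lesion_depth(a) == pytest.approx(max_lesion_depth(b), abs=H)
    assert max_continuous_circumferential_depth(a) == pytest.approx(
        max_continuous_circumferential_depth(b), abs=H
    )


def test_report_internal_consistency(annulus):
    rep = lesion_report(annulus)
    assert rep.max_continuous_circumferential_depth <= rep.max_depth <= 10.0
    assert (len(rep.gap_angles) == 0) == rep.surface_ring_closed
    ela = annulus_mask_stack(h=H, depth=2.0)
    rep2 = lesion_report(ela)
    assert rep2.max_continuous_circumferential_depth <= rep2.max_depth
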