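"""Rasterisation of the tissue + catheter phantom."""

import numpy as np
import pytest

import pfasim as pf
from pfasim.config import LABEL_BLOOD, LABEL_CATHETER, LABEL_MYOCARDIUM, ELECTRODE_BASE
from pfasim.phantom import GeometryError

from conftest import coarse_geometry


def test_myocardial_volume_matches_analytic():
    """ROI myocardial volume: slab minus the 25 mm lumen, within 2%."""
    config = pf.GeometryConfig(voxel_size=0.25, voxel_size_z=0.25)
    phantom = pf.build_phantom(config)
    grid = phantom.grid
    vol = grid.cell_volumes()
    half = config.roi_halfwidth
    in_roi = (
        (np.abs(grid.x_centers)[:, None, None] <= half)
        & (np.abs(grid.y_centers)[None, :, None] <= half)
    )
    myo = (phantom.label_grid == LABEL_MYOCARDIUM) & in_roi
    measured = float(vol[myo].sum())
    analytic = ((2 * half) ** 2 - np.pi * config.vein_radius**2) * config.myocardium_thickness
    assert measured == pytest.approx(analytic, rel=0.02)


def test_zero_vein_diameter_gives_solid_slab():
    config = coarse_geometry(vein_diameter=0.0, flower_outer_diameter=33.0)
    phantom = pf.build_phantom(config)
    below = phantom.grid.z_centers < 0
    sub = phantom.label_grid[:, :, below]
    r = phantom.grid.radius_xy
    inside = r <= config.domain_radius
    assert not np.any(sub[inside, :] == LABEL_BLOOD)


def test_every_electrode_nonempty_and_connected(coarse_phantom):
    from scipy import ndimage

    counts = coarse_phantom.electrode_voxel_counts()
    assert set(counts) == set(range(1, 21))
    assert min(counts.values()) >= 4
    for eid in (1, 7, 20):
        mask = coarse_phantom.electrode_mask(eid)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1


def test_labels_partition_and_material_lookup_pure(coarse_phantom, coarse_config):
    labels = coarse_phantom.label_grid
    assert labels.min() >= 0
    rebuilt = pf.build_phantom(coarse_config)
    assert np.array_equal(rebuilt.label_grid, labels)
    assert np.array_equal(rebuilt.sigma_grid, coarse_phantom.sigma_grid)
    # conductivity is a pure function of the label
    sig = coarse_phantom.sigma_grid
    for lab, name in [(LABEL_BLOOD, "blood"), (LABEL_MYOCARDIUM, "myocardium")]:
        assert np.all(sig[labels == lab] == coarse_phantom.materials.conductivity[name])


def test_seventy_two_degree_symmetry_up_to_rasterisation():
    """Rebuilding at pose 72 equals rotating the pose-0 phantom by 72
    degrees, electrode identity permuted, within rasterisation error."""
    from scipy.ndimage import map_coordinates

    config = coarse_geometry(voxel_size=0.5, voxel_size_z=0.5)
    p0 = pf.build_phantom(config)
    p72 = pf.build_phantom(config, layout=pf.place_catheter(config, 72.0))

    # per-electrode voxel counts map to the 72-degree partner
    c0 = p0.electrode_voxel_counts()
    c72 = p72.electrode_voxel_counts()
    for spline in range(1, 6):
        partner = spline % 5 + 1
        for pos in range(1, 5):
            eid = (spline - 1) * 4 + pos
            pid = (partner - 1) * 4 + pos
            assert c72[pid] == pytest.approx(c0[eid], rel=0.35, abs=4)

    # catheter+electrode occupancy matches after nearest-neighbour rotation
    solid0 = (p0.label_grid >= LABEL_CATHETER).astype(float)
    solid72 = p72.label_grid >= LABEL_CATHETER
    grid = p0.grid
    theta = np.deg2rad(72.0)
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    xs = np.cos(theta) * X + np.sin(theta) * Y
    ys = -np.sin(theta) * X + np.cos(theta) * Y
    fi = np.interp(xs, grid.x_centers, np.arange(len(grid.x_centers)))
    fj = np.interp(ys, grid.y_centers, np.arange(len(grid.y_centers)))
    rotated = np.empty_like(solid0, dtype=bool)
    for k in range(solid0.shape[2]):
        rotated[:, :, k] = (
            map_coordinates(solid0[:, :, k], [fi, fj], order=0, mode="nearest") > 0.5
        )
    mismatch = np.logical_xor(rotated, solid72).sum()
    assert mismatch <= 0.2 * max(solid72.sum(), 1)


def test_label_volumes_stable_under_refinement():
    """Tissue volumes move < 2% when the voxel size is halved."""
    vols = {}
    for h in (1.0, 0.5):
        config = coarse_geometry(voxel_size=h, voxel_size_z=h / 2, contact_embed=h / 2)
        vols[h] = pf.build_phantom(config).label_volumes()
    for lab in (LABEL_BLOOD, LABEL_MYOCARDIUM):
        assert vols[0.5][lab] == pytest.approx(vols[1.0][lab], rel=0.02)


def test_overlapping_electrodes_raise():
    import dataclasses

    config = coarse_geometry()
    layout = pf.place_catheter(config)
    clone = dataclasses.replace(layout.electrodes[1], center=layout.electrodes[0].center.copy())
    bad = pf.CatheterLayout(
        electrodes=(layout.electrodes[0], clone) + layout.electrodes[2:],
        spline_curves=layout.spline_curves,
        pose_angle=0.0,
        plane_z=layout.plane_z,
    )
    with pytest.raises(GeometryError):
        pf.build_phantom(config, layout=bad)
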