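"""Layout geometry of the five-petal flower catheter."""

import numpy as np
import pytest

import pfasim as pf
from pfasim.catheter import parse_address
from pfasim.config import ConfigError

from conftest import coarse_geometry


@pytest.fixture(scope="module")
def layout():
    return pf.place_catheter(pf.GeometryConfig())


def test_electrode_count_and_uniqueness(layout):
    assert len(layout.electrodes) == 20
    per_spline = {}
    for e in layout.electrodes:
        per_spline.setdefault(e.spline_id, []).append(e.position_id)
    assert set(per_spline) == {1, 2, 3, 4, 5}
    assert all(sorted(v) == [1, 2, 3, 4] for v in per_spline.values())
    # pairwise non-overlap: centre separation beyond one electrode diameter
    centers = np.array([e.center for e in layout.electrodes])
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() > layout.electrodes[0].diameter


def test_arc_spacing_is_electrode_pitch(layout):
    """Consecutive electrode centres sit one pitch (electrode length +
    end gap = 5 mm) apart along the petal arc; chords are shorter on a
    curved petal, so the distance is measured along the curve."""
    config = pf.GeometryConfig()
    curve = layout.spline_curves[0]
    seg = np.diff(curve[:, :2], axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    def arc_of(e):
        d = np.linalg.norm(curve[:, :2] - e.center[:2], axis=1)
        return s[int(np.argmin(d))]

    es = sorted(
        (e for e in layout.electrodes if e.spline_id == 1),
        key=lambda e: e.position_id,
    )
    arcs = [arc_of(e) for e in es]
    for a1, a2 in zip(arcs, arcs[1:]):
        assert abs(a2 - a1) == pytest.approx(config.electrode_pitch, abs=0.1)
    # chords never exceed the arc spacing
    for e1, e2 in zip(es, es[1:]):
        assert np.linalg.norm(e2.center - e1.center) <= config.electrode_pitch + 1e-9


def test_tip_electrodes_are_radially_outermost(layout):
    radii = {
        e.position_id: np.hypot(e.center[0], e.center[1])
        for e in layout.electrodes
        if e.spline_id == 1
    }
    assert radii[2] > radii[1] and radii[3] > radii[4]
    assert radii[2] == pytest.approx(radii[3], abs=1e-9)
    assert radii[1] == pytest.approx(radii[4], abs=1e-9)


def test_five_fold_symmetry(layout):
    """Rotating by 72 degrees maps spline s to s+1 preserving position."""
    rotated = layout.rotated(72.0)
    for e in layout.electrodes:
        partner_spline = e.spline_id % 5 + 1
        partner = next(
            p
            for p in rotated.electrodes
            if p.spline_id == e.spline_id and p.position_id == e.position_id
        )
        original_partner = next(
            p
            for p in layout.electrodes
            if p.spline_id == partner_spline and p.position_id == e.position_id
        )
        assert np.allclose(partner.center, original_partner.center, atol=1e-9)


def test_pose_angle_is_rigid_rotation():
    config = pf.GeometryConfig()
    base = pf.place_catheter(config, 0.0)
    posed = pf.place_catheter(config, 24.0)
    theta = np.deg2rad(24.0)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    for e0, e1 in zip(base.electrodes, posed.electrodes):
        assert np.allclose(e1.center, rot @ e0.center, atol=1e-9)


def test_address_parsing():
    assert parse_address("s1:i") == 1
    assert parse_address("s3:ii") == 10
    assert parse_address("s5:iv") == 20


def test_chain_longer_than_petal_errors():
    config = pf.GeometryConfig(
        flower_outer_diameter=26.0, petal_halfwidth=1.0, hub_radius=11.0
    )
    with pytest.raises(ConfigError):
        pf.place_catheter(config)


def test_voxel_size_must_resolve_electrode():
    with pytest.raises(ConfigError):
        coarse_geometry(voxel_size=2.0)
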