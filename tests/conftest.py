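"""Shared fixtures: coarse study phantoms and analytic oracle phantoms.

The coarse configuration (1 mm in-plane, 0.5 mm vertical) keeps unit
tests fast; quantitative acceptance checks use their own finer session
fixture in test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

import pfasim as pf
from pfasim.config import (
    LABEL_BLOOD,
    LABEL_EXTERIOR,
    LABEL_MYOCARDIUM,
    electrode_label,
)
from pfasim.grid import RectilinearGrid


def coarse_geometry(**overrides) -> pf.GeometryConfig:
    base = dict(voxel_size=1.0, voxel_size_z=0.5, contact_embed=0.5)
    base.update(overrides)
    return pf.GeometryConfig(**base)


@pytest.fixture(scope="session")
def coarse_config() -> pf.GeometryConfig:
    return coarse_geometry()


@pytest.fixture(scope="session")
def coarse_phantom(coarse_config) -> pf.VoxelPhantom:
    return pf.build_phantom(coarse_config)


@pytest.fixture(scope="session")
def mode_a_coarse(coarse_config) -> pf.ModeResult:
    """Mode A solved once on the coarse grid, solution retained."""
    return pf.run_mode(coarse_config, "A", keep_solutions=True)


@pytest.fixture(scope="session")
def mode_b_coarse(coarse_config) -> pf.ModeResult:
    return pf.run_mode(coarse_config, "B", keep_solutions=True)


def uniform_grid(h: float, extent_x, extent_y, extent_z) -> RectilinearGrid:
    def axis(lo, hi):
        n = max(1, round((hi - lo) / h))
        return np.linspace(lo, hi, n + 1)

    return RectilinearGrid(
        x_edges=axis(*extent_x), y_edges=axis(*extent_y), z_edges=axis(*extent_z)
    )


def custom_phantom(grid: RectilinearGrid, labels: np.ndarray,
                   materials: pf.MaterialTable | None = None) -> pf.VoxelPhantom:
    """Phantom with hand-built labels (for closed-form oracle problems)."""
    return pf.VoxelPhantom(
        grid=grid,
        label_grid=labels.astype(np.int16),
        config=pf.GeometryConfig(),
        materials=materials or pf.MaterialTable(),
        layout=pf.place_catheter(pf.GeometryConfig()),
    )


def parallel_plate_phantom(h: float = 0.25, side: float = 5.0, gap: float = 10.0):
    """Two full-plane plate electrodes spanning a homogeneous slab.

    Electrode 1 (bottom layer) and 2 (top layer); myocardium between.
    Returns (phantom, tissue_gap_mm): platinum is a near-perfect
    conductor, so the whole potential drop happens across the tissue
    between the plates' inner faces.
    """
    grid = uniform_grid(h, (0, side), (0, side), (0, gap))
    labels = np.full(grid.shape, LABEL_MYOCARDIUM, dtype=np.int16)
    labels[:, :, 0] = electrode_label(1)
    labels[:, :, -1] = electrode_label(2)
    d = float(grid.z_edges[-2] - grid.z_edges[1])
    return custom_phantom(grid, labels), d


def concentric_cylinder_phantom(h: float = 0.25, a: float = 3.0, b: float = 8.0,
                                halfspan: float = 10.0, nz: int = 4):
    """Inner disk electrode (radius a) and outer ring electrode (radius b)
    in a homogeneous medium; exterior beyond the ring."""
    grid = uniform_grid(h, (-halfspan, halfspan), (-halfspan, halfspan), (0, nz * h))
    r = grid.radius_xy
    labels = np.full(grid.shape, LABEL_MYOCARDIUM, dtype=np.int16)
    labels[r <= a, :] = electrode_label(1)
    ring = (r >= b) & (r <= b + 1.5)
    labels[ring, :] = electrode_label(2)
    labels[r > b + 1.5, :] = LABEL_EXTERIOR
    return custom_phantom(grid, labels)


def annulus_mask_stack(
    h: float = 0.25,
    r_in: float = 13.0,
    r_out: float = 24.0,
    depth: float | None = None,
    halfspan: float = 28.0,
    thickness: float = 10.0,
    vein_radius: float = 12.5,
    reporting_radius: float = 26.0,
) -> pf.ELAMask:
    """Rasterised annular lesion from the surface down to ``depth``
    (all layers if None) — the workhorse analytic lesion shape."""
    grid = uniform_grid(h, (-halfspan, halfspan), (-halfspan, halfspan), (-thickness, 0))
    r = grid.radius_xy
    ann = (r >= r_in) & (r <= r_out)
    mask = np.zeros(grid.shape, dtype=bool)
    for k, z in enumerate(grid.z_centers):
        d = -z
        if depth is None or d <= depth:
            mask[:, :, k] = ann
    return pf.ELAMask(
        mask=mask,
        grid=grid,
        vein_radius=vein_radius,
        reporting_radius=reporting_radius,
        myocardium_thickness=thickness,
    )
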