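"""Voxelised tissue + catheter phantom.

The phantom is the synthetic-data generator for the whole pipeline: a
labelled rectilinear voxel grid of blood, myocardium, catheter polymer
and 20 individually identified platinum electrodes, with per-voxel
conductivity and relative permittivity derived from the material table.

Geometry (cell-centre classification):

* myocardium: the slab ``-H2 <= z < 0`` minus the vein lumen cylinder
  of diameter D1 (the lumen is blood down to the slab bottom);
* blood: the lumen plus everything above ``z = 0`` up to the blood top;
* exterior: outside the cylindrical 200 mm domain (zero conductivity,
  which the finite-volume solver treats as a no-flux boundary);
* catheter/electrodes: capsules painted along the petal polylines and
  electrode segments, overwriting tissue labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .catheter import CatheterLayout, place_catheter
from .config import (
    ELECTRODE_BASE,
    LABEL_BLOOD,
    LABEL_CATHETER,
    LABEL_EXTERIOR,
    LABEL_MYOCARDIUM,
    GeometryConfig,
    MaterialTable,
    electrode_label,
)
from .grid import RectilinearGrid, build_grid


class GeometryError(ValueError):
    """Raised when rasterisation produces an inconsistent phantom."""


class ResolutionError(GeometryError):
    """Raised when the voxel grid cannot resolve an electrode."""


@dataclass(frozen=True)
class VoxelPhantom:
    """Labelled voxel model plus material property grids."""

    grid: RectilinearGrid
    label_grid: np.ndarray  # int16, shape grid.shape
    config: GeometryConfig
    materials: MaterialTable
    layout: CatheterLayout
    myocardial_surface_z: float = 0.0

    @property
    def vein_axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, direction) of the pulmonary-vein axis."""
        return np.zeros(3), np.array([0.0, 0.0, 1.0])

    @cached_property
    def sigma_grid(self) -> np.ndarray:
        """Per-voxel conductivity (S/m); 0 marks exterior cells."""
        return _property_lookup(self.label_grid, self.materials.conductivity, 0.0)

    @cached_property
    def epsr_grid(self) -> np.ndarray:
        """Per-voxel relative permittivity; 1 for exterior cells."""
        return _property_lookup(
            self.label_grid, self.materials.relative_permittivity, 1.0
        )

    @cached_property
    def myocardium_mask(self) -> np.ndarray:
        return self.label_grid == LABEL_MYOCARDIUM

    def electrode_mask(self, eid: int) -> np.ndarray:
        return self.label_grid == electrode_label(eid)

    def electrode_voxel_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.label_grid, return_counts=True)
        return {
            int(lab - ELECTRODE_BASE): int(cnt)
            for lab, cnt in zip(labels, counts)
            if lab > ELECTRODE_BASE
        }

    def label_volumes(self) -> dict[int, float]:
        """Voxel volume (mm^3) per label value."""
        vol = self.grid.cell_volumes()
        out: dict[int, float] = {}
        for lab in np.unique(self.label_grid):
            out[int(lab)] = float(vol[self.label_grid == lab].sum())
        return out


def _property_lookup(
    label_grid: np.ndarray, table, exterior_value: float
) -> np.ndarray:
    lut = np.empty(ELECTRODE_BASE + 21, dtype=float)
    lut[LABEL_EXTERIOR] = exterior_value
    lut[LABEL_BLOOD] = table["blood"]
    lut[LABEL_MYOCARDIUM] = table["myocardium"]
    lut[LABEL_CATHETER] = table["catheter"]
    lut[ELECTRODE_BASE:] = table["electrode"]
    return lut[label_grid]


def _capsule_mask(
    grid: RectilinearGrid,
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Boolean mask (over a bounding-box subgrid) of cells whose centre
    lies within ``radius`` of the segment p0-p1."""
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    sl = grid.index_box(lo, hi)
    X = grid.x_centers[sl[0]][:, None, None]
    Y = grid.y_centers[sl[1]][None, :, None]
    Z = grid.z_centers[sl[2]][None, None, :]
    d = p1 - p0
    ll = float(d @ d)
    if ll == 0.0:
        dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
        dist2 = dx * dx + dy * dy + dz * dz
    else:
        t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / ll
        t = np.clip(t, 0.0, 1.0)
        dx = X - (p0[0] + t * d[0])
        dy = Y - (p0[1] + t * d[1])
        dz = Z - (p0[2] + t * d[2])
        dist2 = dx * dx + dy * dy + dz * dz
    return sl, dist2 <= radius * radius


def _paint_polyline(
    labels: np.ndarray,
    grid: RectilinearGrid,
    points: np.ndarray,
    radius: float,
    value: int,
) -> None:
    step = max(1, int(np.ceil(len(points) / 256)))
    pts = points[::step]
    if not np.array_equal(pts[-1], points[-1]):
        pts = np.vstack([pts, points[-1]])
    for p0, p1 in zip(pts[:-1], pts[1:]):
        sl, mask = _capsule_mask(grid, p0, p1, radius)
        labels[sl][mask] = value


def build_phantom(
    config: GeometryConfig,
    materials: MaterialTable | None = None,
    layout: CatheterLayout | None = None,
    grid: RectilinearGrid | None = None,
) -> VoxelPhantom:
    """Rasterise tissue layers, catheter body and electrodes.

    Electrodes are painted last so they overwrite the spline polymer;
    overlapping electrode footprints or an electrode with no voxels
    raise :class:`GeometryError` / :class:`ResolutionError`.
    """
    materials = materials or MaterialTable()
    layout = layout or place_catheter(config)
    grid = grid or build_grid(config)

    nx, ny, nz = grid.shape
    labels = np.empty(grid.shape, dtype=np.int16)

    r_xy = grid.radius_xy  # (nx, ny)
    z = grid.z_centers
    below_surface = z < 0.0
    inside_domain = r_xy <= config.domain_radius
    in_lumen = r_xy < config.vein_radius

    labels[...] = LABEL_BLOOD
    myo_2d = inside_domain & ~in_lumen
    labels[:, :, below_surface] = np.where(
        myo_2d[:, :, None], LABEL_MYOCARDIUM, LABEL_BLOOD
    )
    labels[~inside_domain, :] = LABEL_EXTERIOR

    # Catheter body: petal loops plus the vertical shaft in the blood.
    for curve in layout.spline_curves:
        _paint_polyline(labels, grid, curve, config.electrode_radius, LABEL_CATHETER)
    shaft_top = np.array([0.0, 0.0, 0.9 * config.blood_height])
    shaft_bot = np.array([0.0, 0.0, layout.plane_z])
    sl, mask = _capsule_mask(grid, shaft_bot, shaft_top, config.electrode_radius)
    labels[sl][mask] = LABEL_CATHETER

    # Electrodes: capsules of overall length `length` (core + caps).
    for seg in layout.electrodes:
        half_core = max(0.0, 0.5 * (seg.length - seg.diameter))
        p0 = seg.center - half_core * seg.tangent
        p1 = seg.center + half_core * seg.tangent
        sl, mask = _capsule_mask(grid, p0, p1, 0.5 * seg.diameter)
        target = labels[sl]
        clash = target[mask]
        other = clash[(clash > ELECTRODE_BASE)]
        if other.size:
            raise GeometryError(
                f"electrode {seg.address} overlaps electrode voxels "
                f"already labelled {sorted(set(int(o - ELECTRODE_BASE) for o in other))}"
            )
        if not mask.any():
            raise ResolutionError(
                f"electrode {seg.address} rasterised to zero voxels; "
                "refine voxel_size"
            )
        target[mask] = electrode_label(seg.electrode_id)
        labels[sl] = target

    return VoxelPhantom(
        grid=grid,
        label_grid=labels,
        config=config,
        materials=materials,
        layout=layout,
    )
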