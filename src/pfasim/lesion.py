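"""Effective-lesion-area (ELA) metrics around the vein orifice.

The ELA is the myocardial region where the field magnitude reaches the
irreversible-electroporation threshold (400 V/cm by default).  The
clinically meaningful questions about it are geometric:

* how wide is the lesion band on the myocardial surface,
* how deep does any part of it reach,
* down to what depth does it form a *closed ring* around the vein
  orifice (the isolation criterion), and
* where are the angular gaps when the ring is open.

Ring closure is operationalised as topological separation: a layer is
closed iff non-lesion tissue cannot connect the vein rim to the outer
reporting radius.  The flood fill runs over non-lesion cells with
8-connectivity, so a single-voxel diagonal leak already counts as a gap
— the conservative reading of "continuous".
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage

from .grid import RectilinearGrid

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ELAMask:
    """Binary lesion mask over myocardial voxels, plus context.

    ``reporting_radius`` bounds all circumferential analyses so the far
    field is never mistaken for lesion boundary.
    """

    mask: np.ndarray
    grid: RectilinearGrid
    vein_radius: float
    reporting_radius: float
    myocardium_thickness: float
    surface_z: float = 0.0
    angular_resolution: float = 0.5  # degrees
    min_gap_deg: float = 1.0  # ignore narrower angular gaps (rasterization noise)

    @classmethod
    def from_result(cls, result, mask: np.ndarray | None = None) -> "ELAMask":
        """Wrap a :class:`~pfasim.modes.ModeResult` (or rotation union)."""
        config = result.phantom.config
        grid = result.phantom.grid
        m = mask if mask is not None else result.mask
        return cls(
            mask=m,
            grid=grid,
            vein_radius=config.vein_radius,
            reporting_radius=config.reporting_radius,
            myocardium_thickness=config.myocardium_thickness,
        )

    # -- layers ---------------------------------------------------------
    def myocardial_layers(self) -> list[int]:
        """z-layer indices inside the myocardium, surface first."""
        z = self.grid.z_centers
        sel = np.where(
            (z < self.surface_z) & (z > self.surface_z - self.myocardium_thickness)
        )[0]
        return list(sel[np.argsort(-z[sel])])

    def layer_at_depth(self, depth: float) -> int:
        """z-layer index at ``depth`` mm below the myocardial surface."""
        z = self.surface_z - max(depth, 0.0) - 1e-9
        return self.grid.z_layer_index(z)

    def _in_plane_radius(self) -> np.ndarray:
        return self.grid.radius_xy


def max_lesion_depth(ela: ELAMask) -> float:
    """Deepest lesion extent below the surface, mm (0 for empty mask)."""
    if not ela.mask.any():
        return 0.0
    z = ela.grid.z_centers
    occupied = np.flatnonzero(ela.mask.any(axis=(0, 1)))
    zmin = z[occupied].min()
    return float(ela.surface_z - zmin)


def max_surface_width(ela: ELAMask) -> float:
    """Maximum radial lesion extent in the top myocardial layer, mm.

    For each azimuthal bin (``angular_resolution`` degrees) the width is
    outermost minus innermost lesioned radius plus one in-plane voxel
    (the cell footprint); the maximum over bins is returned.
    """
    layers = ela.myocardial_layers()
    if not layers:
        return 0.0
    return layer_width(ela, layers[0])


def layer_width(ela: ELAMask, iz: int) -> float:
    lesion = ela.mask[:, :, iz]
    r2d = ela._in_plane_radius()
    sel = lesion & (r2d <= ela.reporting_radius)
    if not sel.any():
        return 0.0
    xs = ela.grid.x_centers
    ys = ela.grid.y_centers
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    r = r2d[sel]
    theta = np.degrees(np.arctan2(Y[sel], X[sel])) % 360.0
    nbins = int(round(360.0 / ela.angular_resolution))
    bins = np.minimum((theta / 360.0 * nbins).astype(int), nbins - 1)
    rmin = np.full(nbins, np.inf)
    rmax = np.full(nbins, -np.inf)
    np.minimum.at(rmin, bins, r)
    np.maximum.at(rmax, bins, r)
    good = np.isfinite(rmax)
    if not good.any():
        return 0.0
    voxel = float(np.median(np.diff(xs[np.abs(xs) < ela.reporting_radius])))
    return float((rmax[good] - rmin[good]).max() + voxel)


def ring_closed(ela: ELAMask, depth: float) -> tuple[bool, list[tuple[float, float]]]:
    """Ring-closure test at ``depth`` mm below the surface.

    Returns ``(closed, gap_angles)``: closed is True iff non-lesion
    cells cannot connect the vein rim to the reporting radius in that
    layer (8-connected flood fill over non-lesion cells).  Gap angles
    are degree intervals whose rays meet no lesion voxel; when the ring
    is open but every ray is covered (a purely diagonal leak) the
    interval of the leaking path is reported instead.
    """
    iz = ela.layer_at_depth(depth)
    return _ring_closed_layer(ela, iz)


def _ring_closed_layer(ela: ELAMask, iz: int) -> tuple[bool, list[tuple[float, float]]]:
    lesion = ela.mask[:, :, iz]
    r2d = ela._in_plane_radius()
    h = float(np.median(np.diff(ela.grid.x_centers[np.abs(ela.grid.x_centers) < ela.reporting_radius])))
    outer_limit = ela.reporting_radius + 3 * h

    domain = r2d <= outer_limit
    free = domain & ~lesion
    seeds = r2d < max(ela.vein_radius - h, 0.0)
    outer = (r2d > ela.reporting_radius) & domain
    if not seeds.any():
        # Degenerate lumen: nothing to encircle.
        return False, [(0.0, 360.0)]

    labels, _ = ndimage.label(free, structure=_STRUCTURE_8)
    seed_labels = np.unique(labels[seeds & free])
    outer_labels = np.unique(labels[outer & free])
    leak = np.intersect1d(seed_labels[seed_labels > 0], outer_labels[outer_labels > 0])
    closed = leak.size == 0
    if closed:
        return True, []

    gaps = _angular_gaps(ela, lesion, r2d)
    if not gaps:
        # Diagonal leak with full angular coverage: report the leak path.
        leak_cells = np.isin(labels, leak) & (r2d >= ela.vein_radius) & (
            r2d <= ela.reporting_radius
        )
        gaps = _covered_intervals(ela, leak_cells)
    return False, gaps


def _angular_gaps(ela: ELAMask, lesion: np.ndarray, r2d: np.ndarray) -> list[tuple[float, float]]:
    sel = lesion & (r2d <= ela.reporting_radius)
    nbins = int(round(360.0 / ela.angular_resolution))
    if not sel.any():
        return [(0.0, 360.0)]
    X, Y = np.meshgrid(ela.grid.x_centers, ela.grid.y_centers, indexing="ij")
    theta = np.degrees(np.arctan2(Y[sel], X[sel])) % 360.0
    bins = np.minimum((theta / 360.0 * nbins).astype(int), nbins - 1)
    covered = np.zeros(nbins, dtype=bool)
    covered[bins] = True
    intervals = _bins_to_intervals(~covered, nbins)
    # Sub-degree empty bins are rasterisation noise on a voxel grid, not
    # lesion gaps; the flood-fill closure test is the authority on leaks.
    return [g for g in intervals if g[1] - g[0] >= ela.min_gap_deg]


def _covered_intervals(ela: ELAMask, cells: np.ndarray) -> list[tuple[float, float]]:
    nbins = int(round(360.0 / ela.angular_resolution))
    if not cells.any():
        return []
    X, Y = np.meshgrid(ela.grid.x_centers, ela.grid.y_centers, indexing="ij")
    theta = np.degrees(np.arctan2(Y[cells], X[cells])) % 360.0
    bins = np.minimum((theta / 360.0 * nbins).astype(int), nbins - 1)
    hit = np.zeros(nbins, dtype=bool)
    hit[bins] = True
    return _bins_to_intervals(hit, nbins)


def _bins_to_intervals(flags: np.ndarray, nbins: int) -> list[tuple[float, float]]:
    """Consecutive True bins -> (start_deg, end_deg) intervals, merging
    across the 0/360 wrap."""
    if not flags.any():
        return []
    if flags.all():
        return [(0.0, 360.0)]
    width = 360.0 / nbins
    idx = np.flatnonzero(flags)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    intervals = [(run[0] * width, (run[-1] + 1) * width) for run in runs]
    # merge a run ending at 360 with one starting at 0
    if len(intervals) > 1 and intervals[0][0] == 0.0 and intervals[-1][1] == 360.0:
        first = intervals.pop(0)
        last = intervals.pop()
        intervals.append((last[0], first[1] + 360.0))
    return intervals


def max_continuous_circumferential_depth(
    ela: ELAMask, convention: str = "contiguous_from_surface"
) -> float:
    """Deepest extent of the closed-ring region, mm.

    Default convention: the largest d such that *every* layer from the
    surface down to d is closed (an open surface gives 0).  The
    alternative ``"deepest_closed"`` reports the depth of the deepest
    closed layer regardless of contiguity, for sensitivity analysis.
    """
    layers = ela.myocardial_layers()
    z = ela.grid.z_centers
    depth = 0.0
    deepest = 0.0
    for iz in layers:
        closed, _ = _ring_closed_layer(ela, iz)
        # cell-centre convention, matching max_lesion_depth, so the
        # invariant continuous depth <= max depth holds exactly
        layer_depth = float(ela.surface_z - z[iz])
        if convention == "contiguous_from_surface":
            if not closed:
                break
            depth = layer_depth
        else:
            if closed:
                deepest = layer_depth
    return depth if convention == "contiguous_from_surface" else deepest


@dataclass(frozen=True)
class LesionReport:
    """Scalar lesion metrics plus the per-layer closure profile."""

    max_surface_width: float
    max_depth: float
    max_continuous_circumferential_depth: float
    gap_angles: tuple[tuple[float, float], ...]
    ring_closed_profile: tuple[tuple[float, bool], ...]  # (layer-centre depth, closed)
    surface_ring_closed: bool
    ring_closed_at_3mm: bool
    n_voxels: int
    volume_mm3: float

    def as_dict(self) -> dict:
        return {
            "max_surface_width_mm": self.max_surface_width,
            "max_depth_mm": self.max_depth,
            "max_continuous_circumferential_depth_mm": self.max_continuous_circumferential_depth,
            "surface_ring_closed": self.surface_ring_closed,
            "ring_closed_at_3mm": self.ring_closed_at_3mm,
            "n_gaps": len(self.gap_angles),
            "lesion_volume_mm3": self.volume_mm3,
        }


def lesion_report(ela: ELAMask, slice_depth: float = 3.0) -> LesionReport:
    """Aggregate all lesion metrics (plus the ``slice_depth`` ring check,
    default 3 mm below the surface, the wall-penetration depth of
    interest for thin atrial walls)."""
    layers = ela.myocardial_layers()
    z = ela.grid.z_centers
    profile = []
    for iz in layers:
        closed, _ = _ring_closed_layer(ela, iz)
        profile.append((float(ela.surface_z - z[iz]), closed))
    surface_closed, gaps = (
        _ring_closed_layer(ela, layers[0]) if layers else (False, [(0.0, 360.0)])
    )
    closed_3mm, _ = ring_closed(ela, slice_depth)
    volume = float(ela.grid.cell_volumes()[ela.mask].sum()) if ela.mask.any() else 0.0
    return LesionReport(
        max_surface_width=max_surface_width(ela),
        max_depth=max_lesion_depth(ela),
        max_continuous_circumferential_depth=max_continuous_circumferential_depth(ela),
        gap_angles=tuple(gaps),
        ring_closed_profile=tuple(profile),
        surface_ring_closed=surface_closed,
        ring_closed_at_3mm=closed_3mm,
        n_voxels=int(ela.mask.sum()),
        volume_mm3=volume,
    )


def slice_mask(ela: ELAMask, depth: float) -> np.ndarray:
    """2D lesion mask at ``depth`` mm below the surface (for figures)."""
    return ela.mask[:, :, ela.layer_at_depth(depth)]
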