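"""Rectilinear voxel grid: fine uniform core, geometrically graded shell.

The potential problem must be solved over the full 200 mm domain so the
insulating outer boundary cannot influence the fields near the vein
orifice, but only a ~60 mm region of interest (ROI) around the catheter
needs electrode-resolving voxels.  A tensor-product rectilinear grid
gives both: uniform fine spacing inside the ROI and geometric grading
out to the domain edge.  The two-point-flux finite-volume stencil in
the solver handles the non-uniform spacing exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np


def _graded_edges(start: float, stop: float, h0: float, ratio: float) -> np.ndarray:
    """Edges from ``start`` toward ``stop`` with cell widths growing by
    ``ratio`` from ``h0``; the last cell absorbs the remainder."""
    edges = [start]
    h = h0 * ratio
    pos = start
    direction = 1.0 if stop > start else -1.0
    while True:
        nxt = pos + direction * h
        if direction * (stop - nxt) <= 0.5 * h:
            edges.append(stop)
            break
        edges.append(nxt)
        pos = nxt
        h *= ratio
    return np.asarray(edges)


def make_axis(
    fine_lo: float,
    fine_hi: float,
    h: float,
    domain_lo: float,
    domain_hi: float,
    ratio: float,
) -> np.ndarray:
    """Cell-edge coordinates: uniform ``h`` on [fine_lo, fine_hi], graded
    outside down to ``domain_lo`` and up to ``domain_hi``."""
    n_fine = max(1, round((fine_hi - fine_lo) / h))
    fine = np.linspace(fine_lo, fine_hi, n_fine + 1)
    lower = _graded_edges(fine_lo, domain_lo, h, ratio)[1:] if domain_lo < fine_lo else np.empty(0)
    upper = _graded_edges(fine_hi, domain_hi, h, ratio)[1:] if domain_hi > fine_hi else np.empty(0)
    return np.concatenate([lower[::-1], fine, upper])


@dataclass(frozen=True)
class RectilinearGrid:
    """Cell-centred rectilinear grid defined by its edge coordinates."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    z_edges: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.x_edges) - 1, len(self.y_edges) - 1, len(self.z_edges) - 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @cached_property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @cached_property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @cached_property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @cached_property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @cached_property
    def dy(self) -> np.ndarray:
        return np.diff(self.y_edges)

    @cached_property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    def centers(self, axis: int) -> np.ndarray:
        return (self.x_centers, self.y_centers, self.z_centers)[axis]

    def widths(self, axis: int) -> np.ndarray:
        return (self.dx, self.dy, self.dz)[axis]

    @cached_property
    def radius_xy(self) -> np.ndarray:
        """(nx, ny) array of cell-centre distances from the vein axis."""
        return np.hypot(self.x_centers[:, None], self.y_centers[None, :])

    def cell_volumes(self) -> np.ndarray:
        return (
            self.dx[:, None, None] * self.dy[None, :, None] * self.dz[None, None, :]
        )

    def index_box(
        self, lo: np.ndarray, hi: np.ndarray
    ) -> tuple[slice, slice, slice]:
        """Slices of cells whose centres fall inside an axis-aligned box."""
        slices = []
        for axis, (a, b) in enumerate(zip(lo, hi)):
            c = self.centers(axis)
            i0 = int(np.searchsorted(c, a, side="left"))
            i1 = int(np.searchsorted(c, b, side="right"))
            slices.append(slice(i0, i1))
        return tuple(slices)

    def z_layer_index(self, z: float) -> int:
        """Index of the z layer containing coordinate ``z``."""
        idx = int(np.searchsorted(self.z_edges, z, side="right")) - 1
        return int(np.clip(idx, 0, self.shape[2] - 1))


def build_grid(config) -> RectilinearGrid:
    """Grid for a :class:`~pfasim.config.GeometryConfig`.

    Fine region: |x|,|y| <= roi_halfwidth at ``voxel_size``; z in
    [-myocardium_thickness, roi_top] at ``voxel_size_z``.  Graded shell
    to the 200 mm lateral boundary and the top of the blood layer.  The
    myocardial slab bottom is the domain bottom (insulating), as is the
    blood top.
    """
    r_dom = config.domain_radius
    x_edges = make_axis(
        -config.roi_halfwidth,
        config.roi_halfwidth,
        config.voxel_size,
        -r_dom,
        r_dom,
        config.stretch_ratio,
    )
    z_edges = make_axis(
        -config.myocardium_thickness,
        config.roi_top,
        config.voxel_size_z,
        -config.myocardium_thickness,
        config.blood_height,
        config.stretch_ratio,
    )
    return RectilinearGrid(x_edges=x_edges, y_edges=x_edges.copy(), z_edges=z_edges)
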