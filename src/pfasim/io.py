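"""Volume and table export.

Full-grid exports use the legacy ASCII VTK rectilinear-grid format
(readable by ParaView/VisIt and by pyvista where available), which
represents the non-uniform tensor-product grid exactly.  NIfTI export
resamples nothing: it crops the uniform region of interest and writes
it with its true voxel spacing via nibabel.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .grid import RectilinearGrid


def write_vtk_rectilinear(
    path: str | Path,
    grid: RectilinearGrid,
    cell_fields: Mapping[str, np.ndarray],
    title: str = "pfasim export",
) -> Path:
    """Write cell-centred scalar/vector fields on the rectilinear grid.

    Vector fields are passed with shape (3, nx, ny, nz); scalars with
    the grid shape.
    """
    path = Path(path)
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\n")
        fh.write("DATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        for name, edges in (
            ("X_COORDINATES", grid.x_edges),
            ("Y_COORDINATES", grid.y_edges),
            ("Z_COORDINATES", grid.z_edges),
        ):
            fh.write(f"{name} {len(edges)} float\n")
            fh.write(" ".join(f"{v:.6g}" for v in edges) + "\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, values in cell_fields.items():
            values = np.asarray(values)
            if values.ndim == 4 and values.shape[0] == 3:
                fh.write(f"VECTORS {name} float\n")
                flat = np.stack(
                    [values[c].ravel(order="F") for c in range(3)], axis=1
                )
                np.savetxt(fh, flat, fmt="%.6g")
            else:
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, values.ravel(order="F")[:, None], fmt="%.6g")
    return path


def roi_slices(grid: RectilinearGrid, halfwidth: float, z_lo: float, z_hi: float):
    """Index slices of the uniform ROI block."""
    return grid.index_box(
        np.array([-halfwidth, -halfwidth, z_lo]), np.array([halfwidth, halfwidth, z_hi])
    )


def write_nifti_roi(
    path: str | Path,
    grid: RectilinearGrid,
    values: np.ndarray,
    halfwidth: float,
    z_lo: float,
    z_hi: float,
) -> Path:
    """Write the uniform ROI crop of a cell field as NIfTI (mm spacing)."""
    import nibabel as nib

    sl = roi_slices(grid, halfwidth, z_lo, z_hi)
    block = np.ascontiguousarray(values[sl], dtype=np.float32)
    hx = float(np.median(np.diff(grid.x_centers[sl[0]])))
    hy = float(np.median(np.diff(grid.y_centers[sl[1]])))
    hz = float(np.median(np.diff(grid.z_centers[sl[2]])))
    affine = np.diag([hx, hy, hz, 1.0])
    affine[:3, 3] = [
        grid.x_centers[sl[0]][0],
        grid.y_centers[sl[1]][0],
        grid.z_centers[sl[2]][0],
    ]
    img = nib.Nifti1Image(block, affine)
    img.header.set_zooms((hx, hy, hz))
    nib.save(img, str(path))
    return Path(path)


def write_probe_csv(path: str | Path, profile: np.ndarray, quantity: str = "E_V_per_cm") -> Path:
    """CSV of a depth profile produced by :func:`pfasim.solver.probe_line`."""
    import pandas as pd

    df = pd.DataFrame({"z_mm": profile[:, 0], quantity: profile[:, 1]})
    df.to_csv(path, index=False)
    return Path(path)


def write_gap_csv(path: str | Path, report) -> Path:
    """Polar gap data of a :class:`~pfasim.lesion.LesionReport`: one row
    per surface gap interval plus the per-layer ring-closure profile."""
    import pandas as pd

    gaps = pd.DataFrame(
        list(report.gap_angles) or [],
        columns=["gap_start_deg", "gap_end_deg"],
    )
    profile = pd.DataFrame(
        list(report.ring_closed_profile), columns=["layer_depth_mm", "ring_closed"]
    )
    with open(path, "w") as fh:
        fh.write("# surface gap intervals (degrees)\n")
        gaps.to_csv(fh, index=False)
        fh.write("# ring closure by layer\n")
        profile.to_csv(fh, index=False)
    return Path(path)
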