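"""Quasi-static conduction solver on the voxel phantom.

Solves the current-continuity problem ``div(sigma grad(phi)) = 0`` with
Dirichlet excitation on the driven electrodes and zero normal flux on
the outer domain boundary, then derives the electric field
``E = -grad(phi)`` in V/cm.

Discretisation: cell-centred finite volumes with a 7-point two-point
flux stencil on the rectilinear grid.  Face transmissibilities use the
series (distance-weighted harmonic) conductivity mean, which conserves
flux exactly across material jumps such as platinum/myocardium.  The
resulting system is symmetric positive definite and is solved with a
Jacobi-preconditioned conjugate-gradient iteration — deterministic for
a fixed grid and tolerance.

Driven (positive/ground) electrodes are eliminated as Dirichlet cells
over their whole interior: platinum is a near-perfect conductor, so an
interior Dirichlet is consistent and much better conditioned.  Floating
electrodes stay in the system but each one's cells are merged into a
single unknown (an exact equipotential), which removes the extreme
platinum/tissue conductivity contrast from the iteration.

An optional admittivity variant replaces sigma with the complex
admittivity ``sigma + i 2 pi f eps0 epsr`` at the material-table
frequency, as a sanity check that neglecting the displacement-current
term is harmless; it is informational, not part of the standard solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import electrode_label
from .phantom import VoxelPhantom

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


class SolverError(RuntimeError):
    """Iterative solve failed to reach the requested tolerance."""


@dataclass(frozen=True)
class BoundarySpec:
    """Electrode role assignment for one discharge step.

    Roles are disjoint sets of global electrode ids (1..20): positive
    electrodes are held at ``applied_potential`` volts, ground at 0 V,
    floating electrodes carry no imposed potential (their equipotential
    value emerges from the solve).  Electrodes in no set are treated as
    floating conductors as well.
    """

    positive: frozenset = frozenset()
    ground: frozenset = frozenset()
    floating: frozenset = frozenset()
    applied_potential: float = 900.0

    def __post_init__(self) -> None:
        pos, gnd, flo = (
            frozenset(self.positive),
            frozenset(self.ground),
            frozenset(self.floating),
        )
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "ground", gnd)
        object.__setattr__(self, "floating", flo)
        if pos & gnd or pos & flo or gnd & flo:
            raise ValueError("positive/ground/floating sets must be disjoint")
        if not pos or not gnd:
            raise ValueError("positive and ground sets must both be nonempty")


@dataclass
class ConductionSystem:
    """Assembled sparse system plus the bookkeeping to map back to the grid."""

    phantom: VoxelPhantom
    bc: BoundarySpec
    matrix: sp.csr_matrix
    rhs: np.ndarray
    reduced_index: np.ndarray      # grid -> reduced DOF id, -1 for non-DOF
    dirichlet_values: np.ndarray   # grid of imposed potentials, NaN elsewhere
    transmissibility: list         # per-axis face transmissibility arrays
    sigma: np.ndarray
    complex_valued: bool = False

    @property
    def n_unknowns(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FieldSolution:
    """Potential and derived fields of one discharge step.

    ``phi`` is the cell-centred potential (V); ``E`` stacks the three
    field components (V/cm) and ``magnitude`` their Euclidean norm.
    ``currents`` holds total electrode currents in amperes for the
    conservation check.
    """

    phi: np.ndarray
    E: np.ndarray  # shape (3, nx, ny, nz), V/cm
    magnitude: np.ndarray  # V/cm
    residual: float
    iterations: int
    currents: dict = field(default_factory=dict)
    phantom: VoxelPhantom | None = None
    bc: BoundarySpec | None = None

    def current_density(self) -> np.ndarray:
        """J = sigma * E in A/m^2 (E converted from V/cm)."""
        return self.phantom.sigma_grid * self.magnitude * 100.0


def _face_transmissibility(grid, sigma: np.ndarray, axis: int) -> np.ndarray:
    """Two-point flux transmissibility on interior faces of ``axis``.

    T = area / (d1/(2 s1) + d2/(2 s2)); zero wherever either cell is
    exterior (sigma == 0), which realises the no-flux condition.
    """
    w = grid.widths(axis)
    nd = [1, 1, 1]
    nd[axis] = -1
    half = (0.5 * w).reshape(nd)
    lo = tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))
    hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
    s1, s2 = sigma[lo], sigma[hi]
    h1 = half[tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))]
    h2 = half[tuple(slice(1, None) if a == axis else slice(None) for a in range(3))]
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(np.abs(s1) > 0, h1 / np.where(np.abs(s1) > 0, s1, 1.0), np.inf)
        r2 = np.where(np.abs(s2) > 0, h2 / np.where(np.abs(s2) > 0, s2, 1.0), np.inf)
        T = _face_area(grid, axis) / (r1 + r2)
    T = np.where(np.isfinite(T), T, 0.0)
    return T


def _face_area(grid, axis: int) -> np.ndarray:
    others = [a for a in range(3) if a != axis]
    w0 = grid.widths(others[0])
    w1 = grid.widths(others[1])
    shape0 = [1, 1, 1]
    shape0[others[0]] = -1
    shape1 = [1, 1, 1]
    shape1[others[1]] = -1
    return w0.reshape(shape0) * w1.reshape(shape1)


def assemble_conduction_system(
    phantom: VoxelPhantom,
    bc: BoundarySpec,
    admittivity: bool = False,
    float_conductors: bool = False,
) -> ConductionSystem:
    """Build the reduced SPD system for one discharge step.

    ``float_conductors`` selects how undriven electrodes enter the
    model: as open-circuit elements electrically equivalent to the
    catheter polymer (default — a disconnected electrode on a
    high-impedance generator channel carries no current), or as isolated
    platinum conductors that locally short the field (each merged into
    one equipotential unknown).  The default is the calibrated choice;
    the alternative is kept for sensitivity analysis.

    Raises ``ValueError`` if a boundary set references an electrode with
    no voxels in the phantom.
    """
    grid = phantom.grid
    labels = phantom.label_grid
    sigma = phantom.sigma_grid.astype(complex if admittivity else float)
    if admittivity:
        omega_eps = 2.0 * np.pi * phantom.materials.frequency * EPS0
        sigma = sigma + 1j * omega_eps * phantom.epsr_grid
        sigma[phantom.sigma_grid == 0] = 0.0

    present = set(phantom.electrode_voxel_counts())
    referenced = set(bc.positive) | set(bc.ground) | set(bc.floating)
    missing = referenced - present
    if missing:
        raise ValueError(f"boundary spec references absent electrodes {sorted(missing)}")

    dval = np.full(grid.shape, np.nan)
    for eid in bc.positive:
        dval[labels == electrode_label(eid)] = bc.applied_potential
    for eid in bc.ground:
        dval[labels == electrode_label(eid)] = 0.0

    # Floating electrodes: explicit or simply undriven.
    driven = set(bc.positive) | set(bc.ground)
    float_ids = sorted(present - driven)
    if not float_conductors:
        # Open-circuit treatment: the electrode behaves like the
        # insulating catheter body it is mounted on.
        sigma_polymer = phantom.materials.conductivity["catheter"]
        for eid in float_ids:
            sigma[labels == electrode_label(eid)] = sigma_polymer
        float_ids = []

    active = phantom.sigma_grid > 0
    dirichlet = active & ~np.isnan(dval)
    free = active & ~dirichlet

    reduced = np.full(grid.shape, -1, dtype=np.int64)
    plain_free = free.copy()
    for eid in float_ids:
        plain_free[labels == electrode_label(eid)] = False
    n_plain = int(plain_free.sum())
    reduced[plain_free] = np.arange(n_plain)
    n_red = n_plain
    for eid in float_ids:
        reduced[labels == electrode_label(eid)] = n_red
        n_red += 1

    dtype = complex if admittivity else float
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b = np.zeros(n_red, dtype=dtype)
    T_axes = []
    for axis in range(3):
        T = _face_transmissibility(grid, sigma, axis)
        T_axes.append(T)
        lo = tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
        i1, i2 = reduced[lo], reduced[hi]
        conduct = np.abs(T) > 0
        ff = conduct & (i1 >= 0) & (i2 >= 0)
        r1, r2, t = i1[ff], i2[ff], T[ff]
        rows.extend([r1, r2, r1, r2])
        cols.extend([r2, r1, r1, r2])
        vals.extend([-t, -t, t, t])
        # free cell next to a Dirichlet cell: diagonal + RHS contribution
        for me, other, dv in ((i1, i2, dval[hi]), (i2, i1, dval[lo])):
            fd = conduct & (me >= 0) & (other < 0) & ~np.isnan(dv)
            rows.append(me[fd])
            cols.append(me[fd])
            vals.append(T[fd])
            np.add.at(b, me[fd], T[fd] * dv[fd])

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_red, n_red),
        dtype=dtype,
    ).tocsr()
    A.sum_duplicates()

    return ConductionSystem(
        phantom=phantom,
        bc=bc,
        matrix=A,
        rhs=b,
        reduced_index=reduced,
        dirichlet_values=dval,
        transmissibility=T_axes,
        sigma=sigma,
        complex_valued=admittivity,
    )


class _AggregationMG:
    """Geometric-aggregation multigrid V-cycle, used as a symmetric
    positive-definite preconditioner for conjugate gradients.

    DOFs are aggregated 2x2x2 by their voxel indices (merged floating
    electrodes keep one aggregate each); restriction/prolongation are
    piecewise constant and coarse operators are Galerkin products, so
    the cycle is deterministic and symmetric (damped-Jacobi smoothing,
    one pre- and one post-sweep).
    """

    def __init__(
        self,
        A: sp.csr_matrix,
        coords: np.ndarray,
        omega: float = 0.85,
        coarse_size: int = 20000,
        max_levels: int = 12,
    ):
        self.omega = omega
        self.levels: list[dict] = []
        level_A, level_coords = A, coords
        for _ in range(max_levels):
            n = level_A.shape[0]
            if n <= coarse_size:
                break
            agg_coords = level_coords // 2
            _, agg = np.unique(agg_coords, axis=0, return_inverse=True)
            n_coarse = int(agg.max()) + 1
            if n_coarse >= n:  # no further coarsening possible
                break
            P = sp.csr_matrix(
                (np.ones(n), (np.arange(n), agg)), shape=(n, n_coarse)
            )
            diag = level_A.diagonal()
            self.levels.append(
                {
                    "A": level_A,
                    "P": P,
                    "dinv": np.where(diag != 0, 1.0 / np.where(diag != 0, diag, 1.0), 0.0),
                }
            )
            # coarse coords: centroid voxel index of each aggregate
            sums = np.zeros((n_coarse, 3), dtype=np.int64)
            np.add.at(sums, agg, agg_coords)
            counts = np.bincount(agg, minlength=n_coarse)
            level_coords = sums // counts[:, None]
            level_A = (P.T @ level_A @ P).tocsr()
        self.coarse_solve = spla.factorized(level_A.tocsc())
        self.coarse_A = level_A

    def _cycle(self, level: int, b: np.ndarray) -> np.ndarray:
        if level == len(self.levels):
            return self.coarse_solve(b)
        lv = self.levels[level]
        A, P, dinv = lv["A"], lv["P"], lv["dinv"]
        x = self.omega * dinv * b
        r = b - A @ x
        x = x + P @ self._cycle(level + 1, P.T @ r)
        r = b - A @ x
        x = x + self.omega * dinv * r
        return x

    def __call__(self, b: np.ndarray) -> np.ndarray:
        return self._cycle(0, b)


#: DOF count above which the multigrid preconditioner replaces Jacobi.
_MG_THRESHOLD = 60_000


def solve_potential(
    system: ConductionSystem,
    tol: float = 1e-8,
    maxiter: int = 20000,
) -> FieldSolution:
    """Converged iterative solve; raises :class:`SolverError` otherwise."""
    A, b = system.matrix, system.rhs
    n_iter = 0

    def _count(_):
        nonlocal n_iter
        n_iter += 1

    if np.linalg.norm(b) == 0.0:
        x = np.zeros_like(b)
        rel = 0.0
    else:
        diag = A.diagonal()
        inv = np.where(np.abs(diag) > 0, 1.0 / np.where(np.abs(diag) > 0, diag, 1.0), 1.0)
        if system.complex_valued or A.shape[0] <= _MG_THRESHOLD:
            M = sp.diags(inv)
        else:
            coords = np.argwhere(system.reduced_index >= 0)
            order = system.reduced_index[system.reduced_index >= 0]
            dof_coords = np.empty((A.shape[0], 3), dtype=np.int64)
            dof_coords[order] = coords
            mg = _AggregationMG(A, dof_coords)
            M = spla.LinearOperator(A.shape, matvec=mg)
        if system.complex_valued:
            x, info = spla.bicgstab(A, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M,
                                    callback=_count)
        else:
            x, info = spla.cg(A, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M,
                              callback=_count)
        rel = float(np.linalg.norm(b - A @ x) / np.linalg.norm(b))
        if info != 0:
            raise SolverError(
                f"conjugate gradient did not converge in {maxiter} iterations "
                f"(relative residual {rel:.3e})"
            )

    phi = np.where(np.isnan(system.dirichlet_values), 0.0, system.dirichlet_values)
    phi = phi.astype(x.dtype)
    dof = system.reduced_index >= 0
    phi[dof] = x[system.reduced_index[dof]]

    E, mag = _reconstruct_field(system, phi)
    currents = _electrode_currents(system, phi)

    return FieldSolution(
        phi=phi.real if not system.complex_valued else phi,
        E=E,
        magnitude=mag,
        residual=rel,
        iterations=n_iter,
        currents=currents,
        phantom=system.phantom,
        bc=system.bc,
    )


def _reconstruct_field(system: ConductionSystem, phi: np.ndarray):
    """Flux-consistent cell field: each cell's normal component is the
    face conduction flux divided by the cell's own conductivity, so the
    myocardium-side field is recovered correctly at tissue interfaces
    (a plain central difference would smear the sigma jump).  V/cm.
    """
    grid = system.phantom.grid
    sigma = system.sigma
    shape = grid.shape
    E = np.zeros((3,) + shape, dtype=phi.dtype)
    active = system.phantom.sigma_grid > 0
    for axis in range(3):
        lo = tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
        area = _face_area(grid, axis)
        q = system.transmissibility[axis] * (phi[lo] - phi[hi]) / area  # sigma*E
        qsum = np.zeros(shape, dtype=phi.dtype)
        qsum[lo] += q
        qsum[hi] += q
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = np.where(active, qsum / np.where(active, sigma, 1.0) / 2.0, 0.0)
        E[axis] = comp * 10.0  # V/mm -> V/cm
    mag = np.sqrt(np.abs(E[0]) ** 2 + np.abs(E[1]) ** 2 + np.abs(E[2]) ** 2)
    return E, mag


def _electrode_currents(system: ConductionSystem, phi: np.ndarray) -> dict:
    """Total current leaving positive electrodes / entering grounds (A)."""
    labels = system.phantom.label_grid
    pos = np.isin(labels, [electrode_label(e) for e in system.bc.positive])
    gnd = np.isin(labels, [electrode_label(e) for e in system.bc.ground])
    i_pos = 0.0
    i_gnd = 0.0
    for axis in range(3):
        lo = tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
        T = system.transmissibility[axis]
        dphi = phi[lo] - phi[hi]
        for mask, sgn in (
            ((pos[lo] & ~pos[hi]), 1.0),
            ((pos[hi] & ~pos[lo]), -1.0),
        ):
            i_pos += sgn * np.sum(T[mask] * dphi[mask])
        for mask, sgn in (
            ((gnd[lo] & ~gnd[hi]), -1.0),
            ((gnd[hi] & ~gnd[lo]), 1.0),
        ):
            i_gnd += sgn * np.sum(T[mask] * dphi[mask])
    # T carries sigma (S/m) with mm geometry: scale 1e-3 yields amperes.
    return {"positive": float(np.real(i_pos)) * 1e-3, "ground": float(np.real(i_gnd)) * 1e-3}


def compute_field_vectors(solution: FieldSolution) -> np.ndarray:
    """Per-cell field vectors (3, nx, ny, nz) in V/cm for export."""
    return solution.E


def probe_line(
    solution: FieldSolution,
    x: float,
    y: float,
    quantity: str = "magnitude",
) -> "np.ndarray":
    """|E| (or phi) versus z beneath a surface point, for depth profiles.

    Returns an (n, 2) array of (z, value) at cell centres of the column
    containing (x, y).
    """
    grid = solution.phantom.grid
    i = int(np.clip(np.searchsorted(grid.x_centers, x), 0, grid.shape[0] - 1))
    j = int(np.clip(np.searchsorted(grid.y_centers, y), 0, grid.shape[1] - 1))
    values = solution.magnitude[i, j, :] if quantity == "magnitude" else solution.phi[i, j, :]
    return np.column_stack([grid.z_centers, values])
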