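"""Meshes, time grids, multi-cycle field ensembles and the discrete operators
(gradient, cycle integral, volume/surface integrals) that every haemodynamic
statistic in this package is built from.

Conventions
-----------
* SI units throughout: metres, seconds, Pa, W, J. Velocities in m/s.
* A multi-cycle field ("cycle ensemble") is indexed ``(cycle, phase,
  location, component)``; scalars carry a trailing component axis of size 1.
* Phases live on a grid in ``[0, T)`` and the cardiac cycle is treated as
  periodic: cycle integrals close the loop from the last phase back to the
  first at time ``T``.
* Indices are 0-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeGrid",
    "VolumeMesh",
    "WallSurface",
    "CycleEnsemble",
    "FluidProperties",
    "UnsupportedMeshError",
    "cycle_integral",
    "volume_integral",
    "surface_average",
    "gradient_tensor",
    "node_to_cell",
]


class UnsupportedMeshError(ValueError):
    """Raised when an operation needs structure the mesh does not carry."""


# --------------------------------------------------------------------------
# time grid
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Phase sampling of the cardiac cycle.

    Parameters
    ----------
    period : float
        Cycle period ``T`` in seconds.
    phase_times : ndarray, shape (M,)
        Strictly increasing sample times within ``[0, T)``.
    n_cycles : int
        Number of simulated cycles ``N`` (>= 1).
    """

    period: float
    phase_times: np.ndarray
    n_cycles: int

    def __post_init__(self) -> None:
        times = np.asarray(self.phase_times, dtype=float)
        object.__setattr__(self, "phase_times", times)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if times.ndim != 1 or times.size < 2:
            raise ValueError("need at least 2 phase samples per cycle")
        if np.any(np.diff(times) <= 0):
            raise ValueError("phase_times must be strictly increasing")
        if times[0] < 0 or times[-1] >= self.period:
            raise ValueError("phase_times must lie in [0, T)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @classmethod
    def uniform(cls, period: float, n_phases: int, n_cycles: int) -> "TimeGrid":
        """Uniform phase grid t_m = m T / M (the usual fixed-time-step case)."""
        if n_phases < 2:
            raise ValueError("need at least 2 phases")
        times = np.arange(n_phases) * (period / n_phases)
        return cls(period=period, phase_times=times, n_cycles=n_cycles)

    @property
    def n_phases(self) -> int:
        return self.phase_times.size

    def periodic_weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights for one closed cycle.

        The cycle is periodic, so the interval from the last phase back to
        the first (at time ``T``) is included.  On a uniform grid every
        weight equals ``T / M``.
        """
        t = self.phase_times
        t_ext = np.concatenate([t, [t[0] + self.period]])
        dt = np.diff(t_ext)  # M intervals, closing the cycle
        w = np.zeros(self.n_phases)
        w += 0.5 * dt                    # interval m contributes to phase m
        w += 0.5 * np.roll(dt, 1)        # and to phase m+1 (wrapping)
        return w


def cycle_integral(series: np.ndarray, grid: TimeGrid, axis: int = 0) -> np.ndarray:
    """Integrate a per-phase series over one period with the periodic
    trapezoidal rule (units: input * s).

    On a uniform grid this equals ``T`` times the arithmetic phase mean.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[axis] != grid.n_phases:
        raise ValueError(
            f"series has {series.shape[axis]} phases along axis {axis}, "
            f"grid has {grid.n_phases}"
        )
    w = grid.periodic_weights()
    shape = [1] * series.ndim
    shape[axis] = grid.n_phases
    return np.sum(series * w.reshape(shape), axis=axis)


# --------------------------------------------------------------------------
# geometry carriers
# --------------------------------------------------------------------------


@dataclass
class VolumeMesh:
    """Volume mesh: nodes, hexahedral cells, volumes and centroids.

    ``structured_shape`` marks a structured curvilinear block of nodes
    (e.g. ``(nr, ntheta, nz)``); only such meshes support internal gradient
    evaluation. ``periodic_axes`` lists logical axes that wrap (the
    azimuthal axis of a cylindrical block).
    """

    node_coordinates: np.ndarray            # (P, 3) m
    cell_connectivity: np.ndarray           # (C, 8) node indices
    cell_volumes: np.ndarray                # (C,) m^3
    cell_centroids: np.ndarray              # (C, 3) m
    structured_shape: tuple[int, int, int] | None = None
    periodic_axes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.node_coordinates = np.asarray(self.node_coordinates, dtype=float)
        self.cell_volumes = np.asarray(self.cell_volumes, dtype=float)
        self.cell_centroids = np.asarray(self.cell_centroids, dtype=float)
        if np.any(self.cell_volumes <= 0):
            raise ValueError("all cell volumes must be positive")
        if self.structured_shape is not None:
            p = int(np.prod(self.structured_shape))
            if p != self.n_nodes:
                raise ValueError("structured_shape inconsistent with node count")

    @property
    def n_nodes(self) -> int:
        return self.node_coordinates.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cell_connectivity.shape[0]

    @property
    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())


@dataclass
class WallSurface:
    """Wall surface sampling for wall-shear-stress evaluation.

    ``unit_normals`` point *into* the fluid; ``adjacent_sample_offsets`` are
    the distances along the inward normal at which near-wall velocity is
    sampled (the wall itself is no-slip, velocity zero).
    """

    face_centres: np.ndarray          # (F, 3) m
    unit_normals: np.ndarray          # (F, 3) into the fluid
    face_areas: np.ndarray            # (F,) m^2
    adjacent_sample_offsets: np.ndarray  # (K,) m, increasing, > 0

    def __post_init__(self) -> None:
        self.face_centres = np.asarray(self.face_centres, dtype=float)
        self.unit_normals = np.asarray(self.unit_normals, dtype=float)
        self.face_areas = np.asarray(self.face_areas, dtype=float)
        self.adjacent_sample_offsets = np.asarray(
            self.adjacent_sample_offsets, dtype=float
        )
        norms = np.linalg.norm(self.unit_normals, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("wall normals must be unit vectors (|n| = 1 ± 1e-12)")
        if np.any(self.face_areas <= 0):
            raise ValueError("face areas must be positive")
        if self.adjacent_sample_offsets.size == 0 or np.any(
            self.adjacent_sample_offsets <= 0
        ):
            raise ValueError("need at least one positive near-wall sample offset")

    @property
    def n_faces(self) -> int:
        return self.face_centres.shape[0]


@dataclass(frozen=True)
class FluidProperties:
    """Incompressible Newtonian fluid; defaults are representative of blood."""

    density: float = 1060.0           # kg/m^3
    dynamic_viscosity: float = 0.0035  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


# --------------------------------------------------------------------------
# cycle ensemble
# --------------------------------------------------------------------------


@dataclass
class CycleEnsemble:
    """A field phi(x, t + nT) sampled over cycles, phases and locations.

    ``values`` has shape ``(N, M, L, C)`` — cycle, phase, location,
    component.  ``location_kind`` records whether locations are mesh nodes,
    cells, or wall faces.
    """

    time_grid: TimeGrid
    values: np.ndarray
    units: str = ""
    name: str = ""
    location_kind: str = "node"  # "node" | "cell" | "face"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 3:  # scalar field without component axis
            v = v[..., np.newaxis]
        if v.ndim != 4:
            raise ValueError("values must have shape (cycle, phase, location, comp)")
        if v.shape[0] != self.time_grid.n_cycles:
            raise ValueError("cycle extent does not match time grid")
        if v.shape[1] != self.time_grid.n_phases:
            raise ValueError("phase extent does not match time grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("ensemble values must be finite")
        self.values = v

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]

    @property
    def n_phases(self) -> int:
        return self.values.shape[1]

    @property
    def n_locations(self) -> int:
        return self.values.shape[2]

    @property
    def n_components(self) -> int:
        return self.values.shape[3]

    def cycle(self, n: int) -> np.ndarray:
        """Instantaneous series of cycle ``n``, shape (M, L, C)."""
        return self.values[n]


# --------------------------------------------------------------------------
# integrals
# --------------------------------------------------------------------------


def volume_integral(cell_values: np.ndarray, mesh: VolumeMesh) -> np.ndarray:
    """Sum value * dV over cells; leading axes broadcast (units: value * m^3)."""
    cell_values = np.asarray(cell_values, dtype=float)
    if cell_values.shape[-1] != mesh.n_cells:
        raise ValueError(
            f"got {cell_values.shape[-1]} cell values for {mesh.n_cells} cells"
        )
    return cell_values @ mesh.cell_volumes


def surface_average(face_values: np.ndarray, wall: WallSurface) -> np.ndarray:
    """Area-weighted mean over wall faces; leading axes broadcast."""
    face_values = np.asarray(face_values, dtype=float)
    if face_values.shape[-1] != wall.n_faces:
        raise ValueError(
            f"got {face_values.shape[-1]} face values for {wall.n_faces} faces"
        )
    return (face_values @ wall.face_areas) / wall.face_areas.sum()


def node_to_cell(node_values: np.ndarray, mesh: VolumeMesh) -> np.ndarray:
    """Average nodal values to cells (mean of the 8 hexahedron corners)."""
    node_values = np.asarray(node_values, dtype=float)
    return node_values[..., mesh.cell_connectivity, :].mean(axis=-2)


# --------------------------------------------------------------------------
# gradients on structured curvilinear blocks
# --------------------------------------------------------------------------


def _diff_along(f: np.ndarray, axis: int, periodic: bool) -> np.ndarray:
    """d f / d xi along a logical axis (unit logical spacing).

    Central differences in the interior; periodic wrap or one-sided
    second-order stencils at block boundaries.
    """
    n = f.shape[axis]
    if periodic:
        return 0.5 * (np.roll(f, -1, axis=axis) - np.roll(f, 1, axis=axis))
    if n < 3:
        raise ValueError("need >= 3 points along a non-periodic axis")
    out = np.empty_like(f)

    def sl(idx):
        s = [slice(None)] * f.ndim
        s[axis] = idx
        return tuple(s)

    out[sl(slice(1, -1))] = 0.5 * (f[sl(slice(2, None))] - f[sl(slice(0, -2))])
    out[sl(0)] = -1.5 * f[sl(0)] + 2.0 * f[sl(1)] - 0.5 * f[sl(2)]
    out[sl(-1)] = 1.5 * f[sl(-1)] - 2.0 * f[sl(-2)] + 0.5 * f[sl(-3)]
    return out


def gradient_tensor(mesh: VolumeMesh, node_values: np.ndarray) -> np.ndarray:
    """Velocity-gradient tensor G[i, j] = du_i/dx_j at every node (1/s).

    Works on structured curvilinear blocks: logical-space derivatives of the
    field and of the node coordinates are combined through the inverse
    Jacobian, so the result is expressed in the global Cartesian frame.
    Exact for affine fields; second-order accurate otherwise.

    Parameters
    ----------
    node_values : ndarray, shape (..., P, 3)
        One or more vector fields on the mesh nodes; leading axes (phases,
        cycles) are batched.

    Returns
    -------
    ndarray, shape (..., P, 3, 3)
    """
    if mesh.structured_shape is None:
        raise UnsupportedMeshError(
            "gradient evaluation requires a structured-block mesh; for "
            "unstructured input, supply solver-exported gradient tensors"
        )
    shape = mesh.structured_shape
    node_values = np.asarray(node_values, dtype=float)
    if node_values.shape[-2] != mesh.n_nodes or node_values.shape[-1] != 3:
        raise ValueError("node_values must have shape (..., n_nodes, 3)")

    lead = node_values.shape[:-2]
    f = node_values.reshape(lead + shape + (3,))
    x = mesh.node_coordinates.reshape(shape + (3,))

    # Jacobian J[a, j] = dx_j / dxi_a at each node
    jac = np.stack(
        [_diff_along(x, a, a in mesh.periodic_axes) for a in range(3)], axis=-2
    )  # (*shape, 3(a), 3(j))
    # field derivatives D[a, i] = du_i / dxi_a
    nlead = len(lead)
    dfd = np.stack(
        [_diff_along(f, nlead + a, a in mesh.periodic_axes) for a in range(3)],
        axis=-2,
    )  # (*lead, *shape, 3(a), 3(i))

    # du_i/dx_j solves J^T A^T = D  with A[i, j] = du_i/dx_j:
    # D[a, i] = A[i, j] J[a, j]  =>  A = (J^{-1} D)^T  componentwise per node
    grad_t = np.linalg.solve(np.broadcast_to(jac, dfd.shape), dfd)  # (..., j, i)
    grad = np.swapaxes(grad_t, -1, -2)  # (..., i, j)
    return grad.reshape(lead + (mesh.n_nodes, 3, 3))


# --------------------------------------------------------------------------
# hexahedral volumes (structured-block mesh construction helper)
# --------------------------------------------------------------------------

# six-tetrahedron split of a hexahedron along the main diagonal 0-6
# (node order: binary (di, dj, dk) -> 0:000 1:100 2:110 3:010 4:001 5:101 6:111 7:011)
_HEX_TETS = (
    (0, 1, 2, 6),
    (0, 2, 3, 6),
    (0, 3, 7, 6),
    (0, 7, 4, 6),
    (0, 4, 5, 6),
    (0, 5, 1, 6),
)


def hexahedron_volumes(corners: np.ndarray) -> np.ndarray:
    """Volumes of hexahedral cells, shape (C, 8, 3) -> (C,)."""
    vol = np.zeros(corners.shape[0])
    for a, b, c, d in _HEX_TETS:
        e1 = corners[:, b] - corners[:, a]
        e2 = corners[:, c] - corners[:, a]
        e3 = corners[:, d] - corners[:, a]
        vol += np.abs(np.einsum("ij,ij->i", np.cross(e1, e2), e3)) / 6.0
    return vol


def structured_block_mesh(
    coords: np.ndarray, periodic_axes: Sequence[int] = ()
) -> VolumeMesh:
    """Build a :class:`VolumeMesh` from structured node coordinates.

    Parameters
    ----------
    coords : ndarray, shape (n0, n1, n2, 3)
        Node positions of the block.
    periodic_axes : sequence of int
        Logical axes that wrap around (cells are created across the seam).
    """
    coords = np.asarray(coords, dtype=float)
    n0, n1, n2, _ = coords.shape
    shape = (n0, n1, n2)

    def ravel(i, j, k):
        return (i * n1 + j) * n2 + k

    counts = []
    for a, n in enumerate(shape):
        counts.append(n if a in periodic_axes else n - 1)
    i0 = np.arange(counts[0])
    j0 = np.arange(counts[1])
    k0 = np.arange(counts[2])
    ii, jj, kk = np.meshgrid(i0, j0, k0, indexing="ij")
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()

    def wrap(idx, axis):
        return idx % shape[axis]

    # VTK-style corner ordering consistent with _HEX_TETS
    corner_offsets = [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ]
    conn = np.stack(
        [
            ravel(wrap(ii + di, 0), wrap(jj + dj, 1), wrap(kk + dk, 2))
            for (di, dj, dk) in corner_offsets
        ],
        axis=1,
    )
    nodes = coords.reshape(-1, 3)
    corners = nodes[conn]
    volumes = hexahedron_volumes(corners)
    centroids = corners.mean(axis=1)
    return VolumeMesh(
        node_coordinates=nodes,
        cell_connectivity=conn,
        cell_volumes=volumes,
        cell_centroids=centroids,
        structured_shape=shape,
        periodic_axes=tuple(periodic_axes),
    )
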