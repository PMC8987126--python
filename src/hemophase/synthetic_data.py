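"""Synthetic pulsatile-flow ensembles with known ground truth.

The generator stands in for patient-specific CFD output: the mean flow is
the analytic Womersley solution for pulsatile laminar flow in a rigid
circular pipe (a steady Poiseuille component plus Bessel-function profiles
for each oscillatory harmonic of the prescribed bulk-velocity waveform),
and cycle-to-cycle disturbances are seeded, spatially correlated Gaussian
random fields scaled by a per-phase amplitude envelope sigma(t) that peaks
during systolic deceleration — the timing at which turbulence production
peaks in stenotic aortic flow.  The fluctuations have controllable
two-point structure but make no claim to satisfy the Navier-Stokes
equations.

Everything the post-processing pipeline consumes is produced: the node
velocity ensemble, a near-wall sampling for wall shear stress, the mesh,
wall surface, an ROI partition, a degraded MRI-like voxel reference, and
the analytic ground truth (per-phase wall shear, imposed sigma field,
mean-field dissipation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import jv

from .compare_diagnostics import VoxelGrid, downsample_to_voxels
from .core_fields import (
    CycleEnsemble,
    FluidProperties,
    TimeGrid,
    VolumeMesh,
    WallSurface,
    structured_block_mesh,
)
from .roi_analysis import ROIPartition, partition_by_axial_bins

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "womersley_velocity",
    "womersley_shear_rate",
    "analytic_wall_shear",
    "analytic_mean_dissipation",
    "generate_ensemble",
]

_I32 = np.exp(1j * 3 * np.pi / 4)  # i^(3/2)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a generated dataset.

    The bulk-velocity waveform is ``mean + sum_k amp_k cos(k w t + phase_k)``
    (m/s, cross-section average).  ``sigma_peak`` sets the maximum of the
    Gaussian fluctuation-amplitude envelope, centred at ``sigma_centre``
    (fraction of the period, default in systolic deceleration) with width
    ``sigma_width`` (fraction of the period).  Fluctuations are windowed by
    ``1 - (r/R)^2`` so the no-slip condition is preserved exactly.
    """

    radius: float = 0.012                # m, aortic-scale pipe
    length: float = 0.10                 # m
    fluid: FluidProperties = field(default_factory=FluidProperties)
    waveform_mean: float = 0.12          # m/s bulk velocity, cycle mean
    harmonics: tuple[tuple[float, float], ...] = ((0.25, -np.pi / 2), (0.08, np.pi))
    period: float = 1.0                  # s
    n_phases: int = 50
    n_cycles: int = 30
    grid: tuple[int, int, int] = (32, 24, 64)   # (nr, ntheta, nz)
    radial_stretch: float | None = None  # geometric ratio < 1 refines at wall
    core_radius_frac: float = 0.02       # excluded axis core, fraction of R
    sigma_peak: float = 0.05             # m/s
    sigma_centre: float = 0.30           # fraction of T (systolic deceleration)
    sigma_width: float = 0.08            # fraction of T
    correlation_length: float = 0.002    # m
    seed: int = 0
    mri_n_phases: int = 20
    mri_noise_std: float = 0.0           # m/s, added to the voxel reference

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")
        if self.sigma_peak < 0:
            raise ValueError("sigma envelope must be non-negative")

    def time_grid(self) -> TimeGrid:
        return TimeGrid.uniform(self.period, self.n_phases, self.n_cycles)

    def bulk_waveform(self, t: np.ndarray) -> np.ndarray:
        """Prescribed cross-section-average velocity (m/s) at times t."""
        t = np.asarray(t, dtype=float)
        omega = 2 * np.pi / self.period
        u = np.full(t.shape, self.waveform_mean)
        for k, (amp, ph) in enumerate(self.harmonics, start=1):
            u = u + amp * np.cos(k * omega * t + ph)
        return u

    def sigma_envelope(self, t: np.ndarray | None = None) -> np.ndarray:
        """Fluctuation amplitude sigma(t) (m/s) at the phase times."""
        if t is None:
            t = self.time_grid().phase_times
        t = np.asarray(t, dtype=float)
        tc = self.sigma_centre * self.period
        w = self.sigma_width * self.period
        return self.sigma_peak * np.exp(-0.5 * ((t - tc) / w) ** 2)

    def radial_coordinates(self) -> np.ndarray:
        """Radial node positions from the core radius to the wall."""
        nr = self.grid[0]
        r0 = self.core_radius_frac * self.radius
        if self.radial_stretch is None:
            return np.linspace(r0, self.radius, nr)
        q = self.radial_stretch
        steps = q ** np.arange(nr - 1)
        dr = steps * (self.radius - r0) / steps.sum()
        return np.concatenate([[r0], r0 + np.cumsum(dr)])


# --------------------------------------------------------------------------
# Womersley solution
# --------------------------------------------------------------------------


def _harmonic_profile(spec: SyntheticSpec, k: int, r: np.ndarray) -> np.ndarray:
    """Complex radial profile of harmonic k, normalised to unit bulk mean."""
    omega = 2 * np.pi / spec.period
    alpha = spec.radius * np.sqrt(
        k * omega * spec.fluid.density / spec.fluid.dynamic_viscosity
    )
    lam = _I32 * alpha
    j0 = jv(0, lam)
    d = 1.0 - 2.0 * jv(1, lam) / (lam * j0)
    prof = (1.0 - jv(0, lam * (r / spec.radius)) / j0) / d
    # enforce the analytic no-slip zero exactly (the Bessel evaluation
    # leaves ~1e-16 residue at r = R)
    return np.where(np.asarray(r) == spec.radius, 0.0, prof)


def _harmonic_shear(spec: SyntheticSpec, k: int, r: np.ndarray) -> np.ndarray:
    """Complex d(profile)/dr of harmonic k at radius r."""
    omega = 2 * np.pi / spec.period
    alpha = spec.radius * np.sqrt(
        k * omega * spec.fluid.density / spec.fluid.dynamic_viscosity
    )
    lam = _I32 * alpha
    j0 = jv(0, lam)
    d = 1.0 - 2.0 * jv(1, lam) / (lam * j0)
    return (lam / spec.radius) * jv(1, lam * (r / spec.radius)) / (j0 * d)


def _complex_amplitudes(spec: SyntheticSpec) -> list[complex]:
    """U_k such that bulk(t) = mean + sum Re[U_k e^{i k w t}]."""
    return [amp * np.exp(1j * ph) for (amp, ph) in spec.harmonics]


def womersley_velocity(spec: SyntheticSpec, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Axial velocity u_z(r, t) (m/s) of the analytic pulsatile solution.

    Broadcasts over ``t`` (leading axes) and ``r`` (trailing); the
    cross-section average at every instant equals the prescribed bulk
    waveform by construction.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(r < 0) or np.any(r > spec.radius * (1 + 1e-12)):
        raise ValueError("radial coordinate outside the pipe (0 <= r <= R)")
    omega = 2 * np.pi / spec.period
    u = 2.0 * spec.waveform_mean * (1.0 - (r / spec.radius) ** 2)
    u = np.broadcast_to(u, t.shape + r.shape).copy()
    for k, uk in enumerate(_complex_amplitudes(spec), start=1):
        prof = _harmonic_profile(spec, k, r)
        phase = np.exp(1j * k * omega * t)
        u += np.real(np.multiply.outer(phase, prof) * uk)
    return u


def womersley_shear_rate(spec: SyntheticSpec, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """du_z/dr (1/s) of the analytic solution; broadcasting as above."""
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    omega = 2 * np.pi / spec.period
    dudr = -4.0 * spec.waveform_mean * r / spec.radius**2
    dudr = np.broadcast_to(dudr, t.shape + r.shape).copy()
    for k, uk in enumerate(_complex_amplitudes(spec), start=1):
        dprof = _harmonic_shear(spec, k, r)
        phase = np.exp(1j * k * omega * t)
        dudr += np.real(np.multiply.outer(phase, dprof) * uk)
    return dudr


def analytic_wall_shear(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    """Wall shear stress tau_wall(t) = mu du/dn at r = R (Pa, signed along z).

    Positive when the flow is in +z; the steady part is 4 mu U_mean / R.
    """
    dudr = womersley_shear_rate(spec, np.array([spec.radius]), t)
    return -spec.fluid.dynamic_viscosity * dudr[..., 0]


def analytic_mean_dissipation(
    spec: SyntheticSpec, t: np.ndarray, n_quad: int = 4000
) -> np.ndarray:
    """Viscous dissipation rate (W) of the mean field at times t.

    mu * integral (du/dr)^2 over the full pipe volume, by dense radial
    trapezoidal quadrature of the closed-form shear profile.  For a purely
    steady waveform this is 8 pi mu L U^2.
    """
    t = np.asarray(t, dtype=float)
    r = np.linspace(0.0, spec.radius, n_quad)
    dudr = womersley_shear_rate(spec, r, t)
    integrand = dudr**2 * 2 * np.pi * r
    return spec.fluid.dynamic_viscosity * spec.length * np.trapezoid(integrand, r, axis=-1)


# --------------------------------------------------------------------------
# mesh and wall construction
# --------------------------------------------------------------------------


def cylinder_mesh(spec: SyntheticSpec) -> VolumeMesh:
    """Structured cylindrical block (nr, ntheta, nz), periodic in theta.

    A small axis core (``core_radius_frac`` of R) is excluded because the
    curvilinear coordinate Jacobian is singular on the axis; the dissipation
    density scales as r^2 there, so the truncation is negligible.
    """
    nr, ntheta, nz = spec.grid
    r = spec.radial_coordinates()
    theta = np.arange(ntheta) * (2 * np.pi / ntheta)
    z = np.linspace(0.0, spec.length, nz)
    rr, tt, zz = np.meshgrid(r, theta, z, indexing="ij")
    coords = np.stack([rr * np.cos(tt), rr * np.sin(tt), zz], axis=-1)
    return structured_block_mesh(coords, periodic_axes=(1,))


def cylinder_wall(spec: SyntheticSpec) -> WallSurface:
    """Wall faces at the outer node rings (R, theta_j, z_k), normals inward.

    Near-wall velocity is sampled at the two outermost interior radial node
    rings, so the sample offsets equal the last two radial spacings.
    """
    nr, ntheta, nz = spec.grid
    r = spec.radial_coordinates()
    theta = np.arange(ntheta) * (2 * np.pi / ntheta)
    z = np.linspace(0.0, spec.length, nz)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    centres = np.stack(
        [spec.radius * np.cos(tt), spec.radius * np.sin(tt), zz], axis=-1
    ).reshape(-1, 3)
    normals = np.stack(
        [-np.cos(tt), -np.sin(tt), np.zeros_like(tt)], axis=-1
    ).reshape(-1, 3)
    dz = np.gradient(z)  # half-weight at the axial ends
    areas = (spec.radius * (2 * np.pi / ntheta) * np.broadcast_to(dz, tt.shape)).reshape(-1)
    offsets = np.array([r[-1] - r[-2], r[-1] - r[-3]])
    return WallSurface(
        face_centres=centres,
        unit_normals=normals,
        face_areas=areas,
        adjacent_sample_offsets=offsets,
    )


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Analytic quantities a generated dataset is known to satisfy."""

    wall_shear: np.ndarray          # (M,) Pa, signed along z
    sigma_envelope: np.ndarray      # (M,) m/s
    sigma_window: np.ndarray        # (P,) dimensionless, 1 - (r/R)^2 at nodes
    mean_dissipation: np.ndarray    # (M,) W, full-pipe analytic value
    seed: int = 0

    def sigma_field(self) -> np.ndarray:
        """Imposed pointwise fluctuation std, shape (M, P)."""
        return np.multiply.outer(self.sigma_envelope, self.sigma_window)


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`generate_ensemble`."""

    spec: SyntheticSpec
    time_grid: TimeGrid
    mesh: VolumeMesh
    wall: WallSurface
    ensemble: CycleEnsemble          # node velocities (N, M, P, 3)
    near_wall: np.ndarray            # (N, M, F, 2, 3) velocities at wall offsets
    roi: ROIPartition                # cells
    roi_wall: ROIPartition           # wall faces
    truth: GroundTruth
    mri_grid: VoxelGrid | None = None
    mri_time_grid: TimeGrid | None = None
    mri_velocity: np.ndarray | None = None  # (M_mri, *grid.shape, 3), NaN-masked


def _smoothing_normalisation(shape, sigmas) -> float:
    """Pointwise std of wrap-smoothed unit white noise on this grid."""
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigmas, mode="wrap")
    return float(np.sqrt(np.sum(kernel**2)))


def generate_ensemble(spec: SyntheticSpec, include_mri: bool = True) -> SyntheticDataset:
    """Generate the full synthetic dataset for a spec (deterministic in seed).

    The mean field is the Womersley solution, identical in every cycle;
    fluctuations are zero-mean Gaussian random fields smoothed (with
    periodic wrap) to the target correlation length, normalised to unit
    pointwise variance, scaled by sigma(t) and windowed by 1 - (r/R)^2 so
    the wall remains exactly no-slip.
    """
    nr, ntheta, nz = spec.grid
    grid_shape = (nr, ntheta, nz)
    tg = spec.time_grid()
    rng = np.random.default_rng(spec.seed)

    mesh = cylinder_mesh(spec)
    wall = cylinder_wall(spec)
    r = spec.radial_coordinates()

    # mean field (axial) at nodes, per phase
    profile = womersley_velocity(spec, r, tg.phase_times)  # (M, nr)
    mean_nodes = np.zeros((tg.n_phases, nr, ntheta, nz, 3))
    mean_nodes[..., 2] = profile[:, :, np.newaxis, np.newaxis]

    sigma_t = spec.sigma_envelope()
    window = 1.0 - (r / spec.radius) ** 2  # exactly 0 at the wall
    window3d = window[:, np.newaxis, np.newaxis]

    # grid spacings set the smoothing widths (index units)
    dr = np.diff(r).mean()
    darc = r.mean() * (2 * np.pi / ntheta)
    dz = spec.length / (nz - 1)
    sig_cells = tuple(
        max(spec.correlation_length / h, 1e-6) for h in (dr, darc, dz)
    )
    norm = _smoothing_normalisation(grid_shape, sig_cells)

    values = np.empty((tg.n_cycles, tg.n_phases, nr, ntheta, nz, 3))
    near_idx = (nr - 2, nr - 3)
    for n in range(tg.n_cycles):
        for m in range(tg.n_phases):
            frame = mean_nodes[m].copy()
            if sigma_t[m] > 0:
                for c in range(3):
                    noise = rng.standard_normal(grid_shape)
                    noise = gaussian_filter(noise, sig_cells, mode="wrap") / norm
                    frame[..., c] += sigma_t[m] * window3d * noise
            values[n, m] = frame
    if spec.sigma_peak > 0 and tg.n_cycles == 1:
        import warnings

        warnings.warn(
            "fluctuations are present but unmeasurable with a single cycle",
            stacklevel=2,
        )

    # near-wall samples for WSS: the two outermost interior node rings
    near_wall = np.stack(
        [values[:, :, near_idx[0]], values[:, :, near_idx[1]]], axis=-2
    )  # (N, M, ntheta, nz, 2, 3)
    near_wall = near_wall.reshape(tg.n_cycles, tg.n_phases, ntheta * nz, 2, 3)

    ensemble = CycleEnsemble(
        time_grid=tg,
        values=values.reshape(tg.n_cycles, tg.n_phases, -1, 3),
        units="m/s",
        name="velocity",
        location_kind="node",
    )

    cuts = np.linspace(0.0, spec.length, 5)[1:4]
    roi = partition_by_axial_bins(mesh.cell_centroids, cuts, axis=2)
    roi_wall = partition_by_axial_bins(wall.face_centres, cuts, axis=2)

    truth = GroundTruth(
        wall_shear=analytic_wall_shear(spec, tg.phase_times),
        sigma_envelope=sigma_t,
        sigma_window=np.broadcast_to(window3d, grid_shape).reshape(-1).copy(),
        mean_dissipation=analytic_mean_dissipation(spec, tg.phase_times),
        seed=spec.seed,
    )

    ds = SyntheticDataset(
        spec=spec,
        time_grid=tg,
        mesh=mesh,
        wall=wall,
        ensemble=ensemble,
        near_wall=near_wall,
        roi=roi,
        roi_wall=roi_wall,
        truth=truth,
    )

    if include_mri:
        _attach_mri_reference(ds, rng)
    return ds


def _attach_mri_reference(ds: SyntheticDataset, rng: np.random.Generator) -> None:
    """Voxel-averaged mean field at 20 phases, with optional noise."""
    spec = ds.spec
    mri_tg = TimeGrid.uniform(spec.period, spec.mri_n_phases, 1)
    r = spec.radial_coordinates()
    profile = womersley_velocity(spec, r, mri_tg.phase_times)  # (M_mri, nr)
    nr, ntheta, nz = spec.grid
    nodes = np.zeros((mri_tg.n_phases, nr, ntheta, nz, 3))
    nodes[..., 2] = profile[:, :, np.newaxis, np.newaxis]
    nodes = nodes.reshape(mri_tg.n_phases, -1, 3)

    # lumped node volumes: 1/8 of each adjacent cell
    node_w = np.zeros(ds.mesh.n_nodes)
    np.add.at(node_w, ds.mesh.cell_connectivity.ravel(),
              np.repeat(ds.mesh.cell_volumes / 8.0, 8))

    spacing = 0.0025  # m, typical 4D-flow voxel
    origin = (-spec.radius, -spec.radius, 0.0)
    shape = tuple(
        int(np.ceil(ext / spacing))
        for ext in (2 * spec.radius, 2 * spec.radius, spec.length)
    )
    grid = VoxelGrid(origin=origin, spacing=(spacing,) * 3, shape=shape)

    pts = ds.mesh.node_coordinates
    field_out = np.stack(
        [downsample_to_voxels(pts, nodes[m], node_w, grid) for m in range(mri_tg.n_phases)]
    )
    if spec.mri_noise_std > 0:
        noise = rng.normal(0.0, spec.mri_noise_std, size=field_out.shape)
        field_out = field_out + np.where(np.isfinite(field_out), noise, 0.0)
    ds.mri_grid = grid
    ds.mri_time_grid = mri_tg
    ds.mri_velocity = field_out


def laminar_variant(spec: SyntheticSpec) -> SyntheticSpec:
    """The same spec with fluctuations switched off (sigma = 0)."""
    return replace(spec, sigma_peak=0.0)
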