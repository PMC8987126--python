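"""Wall shear stress metrics: instantaneous WSS from near-wall velocity,
phase-averaged and turbulent WSS, TAWSS, turbulent-TAWSS and the
oscillatory shear index (OSI).

WSS is the tangential traction tau_wall = mu * du/dn exerted by the fluid
on the vessel wall, evaluated here from a one-sided normal derivative of
the near-wall velocity (meshes are assumed wall-resolved; no wall-function
model is provided).  OSI = 0.5 (1 - |integral <WSS> dt| / integral |<WSS>| dt)
lies in [0, 0.5]: 0 for a WSS vector that keeps a fixed direction over the
cycle, 0.5 for a fully oscillatory one.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core_fields import (
    CycleEnsemble,
    FluidProperties,
    TimeGrid,
    WallSurface,
    cycle_integral,
)
from .phase_decomposition import time_average

__all__ = [
    "wss_from_near_wall_velocity",
    "turbulent_wss",
    "tawss",
    "tawss_of_magnitude_mean",
    "turbulent_tawss",
    "osi",
]


def wss_from_near_wall_velocity(
    near_wall_velocity: np.ndarray,
    wall: WallSurface,
    fluid: FluidProperties,
) -> np.ndarray:
    """Instantaneous WSS vectors (Pa) from near-wall velocity samples.

    Parameters
    ----------
    near_wall_velocity : ndarray, shape (..., F, K, 3)
        Velocity at the wall's ``adjacent_sample_offsets`` (K of them,
        along the inward normal); the wall itself is no-slip (zero).
        Leading axes (cycles, phases) are batched.
    wall : WallSurface
    fluid : FluidProperties

    Returns
    -------
    ndarray, shape (..., F, 3)
        Wall-tangential traction mu * (du/dn)_t.  One offset gives a
        first-order one-sided derivative through the no-slip point; two
        offsets give the one-sided second-order (quadratic-fit) derivative.
        The wall-normal component of the traction is discarded.
    """
    u = np.asarray(near_wall_velocity, dtype=float)
    d = wall.adjacent_sample_offsets
    if u.shape[-3] != wall.n_faces or u.shape[-2] != d.size or u.shape[-1] != 3:
        raise ValueError(
            f"near-wall velocity must have shape (..., {wall.n_faces}, "
            f"{d.size}, 3); got {u.shape}"
        )
    if d.size >= 2:
        d1, d2 = d[0], d[1]
        if d2 <= d1:
            raise ValueError("sample offsets must be increasing")
        # quadratic through (0, 0), (d1, u1), (d2, u2): u'(0)
        dudn = (d2**2 * u[..., 0, :] - d1**2 * u[..., 1, :]) / (d1 * d2 * (d2 - d1))
    else:
        dudn = u[..., 0, :] / d[0]
    traction = fluid.dynamic_viscosity * dudn
    n = wall.unit_normals
    normal_part = np.einsum("...fc,fc->...f", traction, n)[..., np.newaxis] * n
    return traction - normal_part


def turbulent_wss(
    wss_vectors: np.ndarray,
    phase_mean_wss: np.ndarray,
    method: str = "vector",
) -> np.ndarray:
    """Turbulent WSS <tau'_wall> per (phase, face): RMS over cycles of the
    deviation from the phase-mean WSS.

    ``method="vector"`` (default) takes the Euclidean norm of the vector
    deviation before squaring — consistent with TKE's sum over components.
    ``method="magnitude"`` uses the deviation of the scalar magnitude about
    its cycle mean instead.

    Parameters
    ----------
    wss_vectors : ndarray, shape (N, M, F, 3)
    phase_mean_wss : ndarray, shape (M, F, 3)
    """
    tau = np.asarray(wss_vectors, dtype=float)
    mean = np.asarray(phase_mean_wss, dtype=float)
    n_cycles = tau.shape[0]
    if n_cycles == 1:
        warnings.warn(
            "turbulent WSS of a single-cycle ensemble is identically zero",
            stacklevel=2,
        )
        return np.zeros(mean.shape[:-1])
    if method == "vector":
        dev = tau - mean
        return np.sqrt(np.einsum("nmfc,nmfc->mf", dev, dev) / n_cycles)
    if method == "magnitude":
        mags = np.linalg.norm(tau, axis=-1)  # (N, M, F)
        mag_mean = mags.mean(axis=0)
        dev = mags - mag_mean
        return np.sqrt((dev**2).mean(axis=0))
    raise ValueError(f"unknown method {method!r}; use 'vector' or 'magnitude'")


def tawss(phase_mean_wss: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Time-averaged WSS (Pa per face): cycle-time average of |<tau_wall>|.

    The magnitude of the phase-mean vector is averaged (the conventional
    TAWSS definition); see :func:`tawss_of_magnitude_mean` for the
    average-of-magnitudes alternative.
    """
    mag = np.linalg.norm(np.asarray(phase_mean_wss, dtype=float), axis=-1)
    return time_average(mag, grid)


def tawss_of_magnitude_mean(wss_vectors: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Alternative TAWSS: time average of the cycle-mean of |tau_wall|."""
    mags = np.linalg.norm(np.asarray(wss_vectors, dtype=float), axis=-1)
    return time_average(mags.mean(axis=0), grid)


def turbulent_tawss(turbulent_wss_series: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Turbulent-TAWSS (Pa per face): cycle-time average of <tau'_wall>."""
    return time_average(np.asarray(turbulent_wss_series, dtype=float), grid)


def osi(wss_series: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Oscillatory shear index per face from a per-phase WSS vector series.

    Parameters
    ----------
    wss_series : ndarray, shape (M, F, 3)
        Phase-mean WSS vectors (or instantaneous final-cycle WSS in the
        instantaneous post-processing mode).

    Returns
    -------
    ndarray, shape (F,), values in [0, 0.5].  Faces with a vanishing
    magnitude integral (no flow) return 0 by convention.
    """
    tau = np.asarray(wss_series, dtype=float)
    vec_int = cycle_integral(tau, grid, axis=0)           # (F, 3)
    mag_int = cycle_integral(np.linalg.norm(tau, axis=-1), grid, axis=0)  # (F,)
    num = np.linalg.norm(vec_int, axis=-1)
    out = np.zeros_like(mag_int)
    nz = mag_int > 0
    out[nz] = 0.5 * (1.0 - num[nz] / mag_int[nz])
    # the triangle inequality bounds num <= mag_int; clip rounding residue
    return np.clip(out, 0.0, 0.5)


def wss_ensemble_from_samples(
    near_wall_ensemble: np.ndarray,
    wall: WallSurface,
    fluid: FluidProperties,
    grid: TimeGrid,
) -> CycleEnsemble:
    """Convenience: wrap per-(cycle, phase) WSS vectors as a CycleEnsemble."""
    tau = wss_from_near_wall_velocity(near_wall_ensemble, wall, fluid)
    return CycleEnsemble(
        time_grid=grid, values=tau, units="Pa", name="wss", location_kind="face"
    )
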