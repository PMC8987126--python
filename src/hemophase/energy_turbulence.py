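"""Volume turbulence and energy statistics: turbulence kinetic energy,
laminar (mean-field) viscous dissipation, turbulent dissipation and net
per-cycle energy losses.

TKE = (rho/2) sum_i <u_i'>^2 is an energy density, reported in Pa.  The
dissipation rates integrate the viscous dissipation function
(mu/2) sum_ij (du_i/dx_j + du_j/dx_i)^2 over the vessel volume and are
reported in W; their cycle integrals are the net energy losses in J.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core_fields import (
    CycleEnsemble,
    FluidProperties,
    TimeGrid,
    VolumeMesh,
    cycle_integral,
    gradient_tensor,
    node_to_cell,
    volume_integral,
)

__all__ = [
    "tke",
    "viscous_dissipation_rate",
    "turbulent_dissipation_rate",
    "net_energy_loss",
    "dissipation_function",
]


def tke(velocity_phase_rms: np.ndarray, fluid: FluidProperties) -> np.ndarray:
    """Turbulence kinetic energy (Pa) from per-component velocity RMS.

    Parameters
    ----------
    velocity_phase_rms : ndarray, shape (..., L, 3)
        Per-phase RMS of the three fluctuating velocity components.

    Returns
    -------
    ndarray, shape (..., L): (rho/2) * sum_i <u_i'>^2.
    """
    rms = np.asarray(velocity_phase_rms, dtype=float)
    if rms.shape[-1] != 3:
        raise ValueError("TKE needs the 3 velocity-component RMS values")
    return 0.5 * fluid.density * np.einsum("...c,...c->...", rms, rms)


def dissipation_function(grad: np.ndarray, fluid: FluidProperties) -> np.ndarray:
    """Pointwise viscous dissipation density (W/m^3) from gradient tensors.

    (mu/2) * sum_ij (G_ij + G_ji)^2 — twice mu times the squared Frobenius
    norm of the strain-rate tensor; zero for rigid-body motion.
    """
    s = grad + np.swapaxes(grad, -1, -2)
    return 0.5 * fluid.dynamic_viscosity * np.einsum("...ij,...ij->...", s, s)


def viscous_dissipation_rate(
    mean_velocity: np.ndarray,
    mesh: VolumeMesh,
    fluid: FluidProperties,
) -> np.ndarray:
    """Laminar viscous dissipation rate (W) per phase from the mean field.

    Parameters
    ----------
    mean_velocity : ndarray, shape (M, P, 3) or (P, 3)
        Phase-mean velocity at mesh nodes (instantaneous velocity in the
        final-cycle post-processing mode).

    Notes
    -----
    The dissipation density is evaluated at nodes from the velocity-gradient
    tensor, averaged to cell centroids, and integrated as density * dV.
    """
    grad = gradient_tensor(mesh, mean_velocity)
    density = dissipation_function(grad, fluid)  # (..., P)
    cell_density = density[..., mesh.cell_connectivity].mean(axis=-1)
    return volume_integral(cell_density, mesh)


def turbulent_dissipation_rate(
    ensemble: CycleEnsemble,
    phase_mean: np.ndarray,
    mesh: VolumeMesh,
    fluid: FluidProperties,
    method: str = "per_cycle",
) -> np.ndarray:
    """Turbulent dissipation rate (W) per phase.

    ``method="per_cycle"`` (default) applies the dissipation function to the
    fluctuating field u' = u - <u> of each cycle separately, then
    phase-averages the result over cycles — a proper second-order
    turbulence statistic.  ``method="rms_gradient"`` instead differentiates
    the RMS field itself; it is NOT equivalent and is provided only for
    comparison with that simplified reading.
    """
    if ensemble.n_components != 3:
        raise ValueError("turbulent dissipation needs a 3-component velocity field")
    if ensemble.n_cycles == 1:
        warnings.warn(
            "turbulent dissipation of a single-cycle ensemble is identically zero",
            stacklevel=2,
        )
        return np.zeros(ensemble.n_phases)

    if method == "per_cycle":
        total = np.zeros(ensemble.n_phases)
        # stream over cycles: gradients of full (M, P, 3, 3) blocks per cycle
        for n in range(ensemble.n_cycles):
            fluct = ensemble.values[n] - phase_mean  # (M, P, 3)
            total += viscous_dissipation_rate(fluct, mesh, fluid)
        return total / ensemble.n_cycles
    if method == "rms_gradient":
        from .phase_decomposition import phase_rms

        rms = phase_rms(ensemble, phase_mean)
        return viscous_dissipation_rate(rms, mesh, fluid)
    raise ValueError(f"unknown method {method!r}; use 'per_cycle' or 'rms_gradient'")


def net_energy_loss(rate_series: np.ndarray, grid: TimeGrid) -> float:
    """Net energy loss per cardiac cycle (J): cycle integral of a rate (W)."""
    return float(cycle_integral(np.asarray(rate_series, dtype=float), grid, axis=0))
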