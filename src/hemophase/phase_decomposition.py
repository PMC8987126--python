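"""Phase-average / fluctuation decomposition of multi-cycle fields.

An instantaneous variable phi(x, t + nT) sampled over N cardiac cycles is
split into a phase-averaged component <phi>(x, t) (arithmetic mean over
cycles at fixed phase) and a fluctuating component phi' whose magnitude is
the per-phase RMS <phi'>(x, t).  The RMS uses the population (1/N) divisor.

Two post-processing modes are supported:

* ``PHASE_AVERAGED`` — the multi-cycle decomposition above; turbulence
  statistics (RMS, TKE, turbulent WSS, turbulent dissipation) are defined.
* ``INSTANTANEOUS_FINAL_CYCLE`` — conventional laminar-style analysis of the
  last simulated cycle only; turbulence statistics are undefined in this
  mode and requesting them raises :class:`ModeIncompatibilityError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_fields import CycleEnsemble, TimeGrid, cycle_integral

__all__ = [
    "AnalysisMode",
    "PhaseStats",
    "ModeIncompatibilityError",
    "phase_average",
    "phase_rms",
    "time_average",
    "decompose",
    "phase_mean_convergence",
]


class AnalysisMode(str, Enum):
    PHASE_AVERAGED = "phase_averaged"
    INSTANTANEOUS_FINAL_CYCLE = "instantaneous_final_cycle"


class ModeIncompatibilityError(RuntimeError):
    """Turbulence statistics requested in instantaneous-final-cycle mode."""


@dataclass
class PhaseStats:
    """Per-phase mean and RMS fluctuation of a cycle ensemble.

    Shapes are ``(M, L, C)`` — phase, location, component.
    """

    phase_mean: np.ndarray
    phase_rms: np.ndarray | None
    n_cycles_used: int

    def __post_init__(self) -> None:
        if self.phase_rms is not None:
            if self.phase_rms.shape != self.phase_mean.shape:
                raise ValueError("phase_rms shape must match phase_mean")
            if np.any(self.phase_rms < 0):
                raise ValueError("phase_rms must be non-negative")


def phase_average(ensemble: CycleEnsemble) -> np.ndarray:
    """Arithmetic mean over cycles at each (phase, location, component)."""
    return ensemble.values.mean(axis=0)


def phase_rms(ensemble: CycleEnsemble, phase_mean: np.ndarray | None = None) -> np.ndarray:
    """Per-phase RMS fluctuation about the phase mean (population divisor N).

    With a single cycle the fluctuation is unmeasurable: returns zeros and
    emits a warning.
    """
    if phase_mean is None:
        phase_mean = phase_average(ensemble)
    if ensemble.n_cycles == 1:
        warnings.warn(
            "phase RMS of a single-cycle ensemble is identically zero "
            "(cycle-to-cycle fluctuation is unmeasurable)",
            stacklevel=2,
        )
        return np.zeros_like(phase_mean)
    # accumulate over cycles to avoid materialising the full deviation array
    acc = np.zeros_like(phase_mean)
    for n in range(ensemble.n_cycles):
        d = ensemble.values[n] - phase_mean
        acc += d * d
    return np.sqrt(acc / ensemble.n_cycles)


def time_average(phase_series: np.ndarray, grid: TimeGrid, axis: int = 0) -> np.ndarray:
    """Cycle integral divided by the period T (periodic trapezoidal rule).

    Applied to <phi> it yields the time-averaged mean quantity; applied to
    <phi'> it yields the time-averaged turbulent quantity.
    """
    return cycle_integral(phase_series, grid, axis=axis) / grid.period


def decompose(
    ensemble: CycleEnsemble, mode: AnalysisMode = AnalysisMode.PHASE_AVERAGED
) -> PhaseStats:
    """Decompose an ensemble under the given post-processing mode.

    Returns phase mean + RMS in phase-averaged mode; in
    instantaneous-final-cycle mode the "mean" series is the last cycle's
    instantaneous values and ``phase_rms`` is ``None``.
    """
    mode = AnalysisMode(mode)
    if mode is AnalysisMode.PHASE_AVERAGED:
        mean = phase_average(ensemble)
        rms = phase_rms(ensemble, mean)
        return PhaseStats(phase_mean=mean, phase_rms=rms, n_cycles_used=ensemble.n_cycles)
    # final cycle only — turbulence undefined
    return PhaseStats(
        phase_mean=ensemble.cycle(ensemble.n_cycles - 1).copy(),
        phase_rms=None,
        n_cycles_used=1,
    )


def require_turbulence(stats: PhaseStats) -> np.ndarray:
    """Return the RMS series or raise if the mode did not produce one."""
    if stats.phase_rms is None:
        raise ModeIncompatibilityError(
            "turbulence-based parameters cannot be calculated from "
            "instantaneous final-cycle values; use phase-averaged mode"
        )
    return stats.phase_rms


def phase_mean_convergence(ensemble: CycleEnsemble) -> float:
    """Convergence-in-N diagnostic for the phase average.

    RMS (over phases, locations, components) of the change in the phase
    mean when the last cycle is added, normalised by the RMS of the mean
    itself.  Small values indicate the N cycles used suffice for the phase
    average of this quantity; no threshold is asserted.
    """
    n = ensemble.n_cycles
    if n < 2:
        raise ValueError("need at least 2 cycles for a convergence diagnostic")
    mean_all = ensemble.values.mean(axis=0)
    mean_head = ensemble.values[:-1].mean(axis=0)
    num = np.sqrt(np.mean((mean_all - mean_head) ** 2))
    den = np.sqrt(np.mean(mean_all**2))
    return float(num / den) if den > 0 else 0.0
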