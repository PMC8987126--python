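# hemophase

Phase-averaged turbulence statistics and haemodynamic metrics for
disturbed pulsatile arterial flow.

Blood flow in large arteries — especially downstream of a stenotic aortic
valve — is not laminar-periodic: it carries cycle-to-cycle fluctuations.
Conventional CFD post-processing analyses only the final simulated cycle
with instantaneous values, which folds those fluctuations into "mean"
quantities and badly inflates gradient-based metrics such as wall shear
stress and viscous energy loss. The statistically correct treatment
decomposes every variable into a phase average over N simulated cycles
and an RMS fluctuation:

    φ(x, t + nT) = ⟨φ⟩(x, t) + φ′(x, t + nT)
    ⟨φ⟩(x, t)  = (1/N) Σₙ φ(x, t + nT)
    ⟨φ′⟩(x, t) = sqrt( (1/N) Σₙ (φ − ⟨φ⟩)² )

`hemophase` implements this decomposition and everything it feeds, for
people running scale-resolving (LES or fine laminar) simulations of
arterial flow:

* **Wall shear stress family** — instantaneous WSS from near-wall
  velocity (τ_wall = μ ∂u/∂n), phase-averaged and turbulent WSS, TAWSS,
  turbulent-TAWSS, and the oscillatory shear index
  OSI = 0.5 (1 − ‖∫⟨WSS⟩dt‖ / ∫‖⟨WSS⟩‖dt) ∈ [0, 0.5].
* **Volume statistics** — turbulence kinetic energy
  TKE = (ρ/2) Σᵢ ⟨uᵢ′⟩² (Pa), laminar and turbulent viscous dissipation
  rates (W) from the velocity-gradient tensor, and net per-cycle energy
  losses (J).
* **Regional analysis** — ROI partitioning (ascending aorta, arch,
  proximal/distal descending aorta by default) with volume- or
  area-weighted spatial averages per phase and in time.
* **Comparison diagnostics** — voxel downsampling to 4D-flow-MRI-like
  resolution with per-component Pearson correlation, and the two-point
  correlation resolution check (≥ 8 cells per largest turbulent scale).
* **Synthetic ensembles** — a Womersley pulsatile-pipe generator with
  seeded, spatially correlated disturbances peaking in systolic
  deceleration, giving ground-truth wall shear, fluctuation amplitude and
  dissipation for every pipeline component.

Both post-processing modes are first-class: `phase_averaged` and
`instantaneous_final_cycle` (the conventional approach), so the effect of
the post-processing choice itself can be quantified. Turbulence metrics
are refused, up front, in final-cycle mode — they are undefined there.

## Worked example

```python
import numpy as np
from hemophase import (SyntheticSpec, generate_ensemble, decompose,
                       wss_from_near_wall_velocity, tawss, turbulent_wss,
                       turbulent_tawss, osi, surface_average)

spec = SyntheticSpec(grid=(16, 12, 24), n_phases=20, n_cycles=16, seed=7)
ds = generate_ensemble(spec, include_mri=False)

tau = wss_from_near_wall_velocity(ds.near_wall, ds.wall, spec.fluid)
tau_phase = tau.mean(axis=0)                       # phase-averaged WSS
print(surface_average(tawss(tau_phase, ds.time_grid), ds.wall))
print(surface_average(osi(tau_phase, ds.time_grid), ds.wall))
turb = turbulent_wss(tau, tau_phase)
print(surface_average(turbulent_tawss(turb, ds.time_grid), ds.wall))
```

prints

```
0.7740016095968493
0.40950674816344496
0.008464904932235022
```

i.e. a surface-mean TAWSS of 0.77 Pa (order 4μU/R for this waveform), a
high surface-mean OSI of 0.41 — the oscillatory harmonics reverse the
wall shear over much of the cycle — and a turbulent-TAWSS of 0.009 Pa,
small because the imposed disturbance is windowed towards zero at the
wall. The `examples/` directory has one short narrative script per
capability (analytic wall shear, decomposition and recovery, WSS metrics,
energy losses and TKE, ROI + MRI comparison, two-point resolution), each
printing the numbers it computes and what they mean.

A thin CLI wraps the same library:

```sh
hemophase simulate --seed 2 --out data/
hemophase run --in data/dataset.h5 --out reports/ --mode phase
hemophase two-point --in data/dataset.h5 --out tp.json
```

## Layout

```
src/hemophase/
  core_fields.py          meshes, time grids, ensembles, operators
  phase_decomposition.py  ⟨φ⟩ / ⟨φ′⟩ machinery and analysis modes
  wss_metrics.py          WSS, TAWSS, turbulent-TAWSS, OSI
  energy_turbulence.py    TKE, dissipation rates, net losses
  roi_analysis.py         ROI partitions and regional reports
  compare_diagnostics.py  voxel downsampling, Pearson, two-point
  synthetic_data.py       Womersley + disturbance generator
  io.py, pipeline.py, cli.py
docs/methods.md           model, assumptions, defaults, limitations
examples/                 one runnable script per capability
```
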