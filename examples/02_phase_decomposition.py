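"""Phase-average / fluctuation decomposition of a disturbed ensemble.

Generates a small multi-cycle dataset with a systolic-deceleration
disturbance burst, decomposes it, and compares the recovered per-phase RMS
with the amplitude that was imposed.
"""

import numpy as np

from hemophase import (
    AnalysisMode,
    SyntheticSpec,
    decompose,
    generate_ensemble,
    phase_mean_convergence,
)

spec = SyntheticSpec(grid=(16, 12, 24), n_phases=20, n_cycles=16, seed=42)
ds = generate_ensemble(spec, include_mri=False)
stats = decompose(ds.ensemble, AnalysisMode.PHASE_AVERAGED)

recovered = stats.phase_rms.mean(axis=(1, 2))        # spatial+component mean
imposed = ds.truth.sigma_field().mean(axis=1)

print(f"{'t [s]':>6} {'imposed sigma':>14} {'recovered RMS':>14}")
for t, imp, rec in zip(ds.time_grid.phase_times, imposed, recovered):
    print(f"{t:6.2f} {imp:14.5f} {rec:14.5f}")

print("\nThe RMS tracks the imposed envelope: fluctuations exist only "
      "around systolic deceleration, where the disturbance was injected.")
print(f"phase-mean convergence diagnostic (relative change adding the "
      f"last cycle): {phase_mean_convergence(ds.ensemble):.2e}")
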