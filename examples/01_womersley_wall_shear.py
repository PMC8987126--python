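"""Analytic pulsatile pipe flow and the wall shear stress it exerts.

Builds the default aortic-scale Womersley flow (mean + two harmonics),
prints the bulk-velocity waveform and the analytic wall shear over the
cycle, and checks the steady part against 4 mu U / R.
"""

import numpy as np

from hemophase import FluidProperties, SyntheticSpec, analytic_wall_shear

spec = SyntheticSpec()
t = np.linspace(0.0, spec.period, 10, endpoint=False)
bulk = spec.bulk_waveform(t)
tau = analytic_wall_shear(spec, t)

alpha = spec.radius * np.sqrt(
    2 * np.pi / spec.period * spec.fluid.density / spec.fluid.dynamic_viscosity
)
print(f"pipe radius {spec.radius*1e3:.1f} mm, period {spec.period:.2f} s, "
      f"Womersley number alpha = {alpha:.1f}")
print(f"{'t [s]':>6} {'bulk U [m/s]':>13} {'tau_wall [Pa]':>14}")
for ti, ui, taui in zip(t, bulk, tau):
    print(f"{ti:6.2f} {ui:13.4f} {taui:14.4f}")

steady = SyntheticSpec(harmonics=(), waveform_mean=0.1, radius=0.01,
                       fluid=FluidProperties())
tau0 = analytic_wall_shear(steady, np.array([0.0]))[0]
print(f"\nsteady check: tau = {tau0:.4f} Pa vs 4*mu*U/R = "
      f"{4*0.0035*0.1/0.01:.4f} Pa")
print("tau_wall swings far beyond its mean because at high Womersley "
      "number the oscillatory boundary layer is thin and steep.")
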