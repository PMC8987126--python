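# Methods

`hemophase` post-processes multi-cycle velocity and wall-shear fields from
scale-resolving cardiovascular CFD. This note records the statistical
model, the numerical choices, what the synthetic data generator does and
does not emulate, and the design decisions taken where more than one
reasonable option existed.

## Phase decomposition

Disturbed pulsatile flow is not periodic cycle to cycle. An instantaneous
variable φ(x, t + nT), sampled at M phases per cycle over N cycles of
period T, is decomposed into a phase-averaged component and a fluctuation:

    φ(x, t + nT) = ⟨φ⟩(x, t) + φ′(x, t + nT)

with the phase average the arithmetic mean over cycles at fixed phase,

    ⟨φ⟩(x, t) = (1/N) Σₙ φ(x, t + nT),

and the fluctuation magnitude the per-phase RMS

    ⟨φ′⟩(x, t) = sqrt( (1/N) Σₙ (φ(x, t + nT) − ⟨φ⟩(x, t))² ).

The RMS uses the **population (1/N) divisor**, with no Bessel correction;
consequently E[⟨φ′⟩²] = σ²(N−1)/N for i.i.d. fluctuations of true variance
σ² (a −3.3 % bias on variance-type quantities at N = 30, and a further
≈ −1/(4N) bias on the RMS itself). This is deliberate: the divisor is part
of the statistic's definition, not an estimator choice, and all derived
turbulence quantities (TKE, turbulent WSS, turbulent dissipation) inherit
it consistently.

Time averages are cycle integrals divided by T. Because the cardiac cycle
is periodic by construction, cycle integrals use the **periodic
trapezoidal rule**, closing the interval from the last phase back to the
first at time T; on a uniform phase grid this equals T times the
arithmetic phase mean, and it integrates trigonometric polynomials of low
order essentially exactly. No quadrature alternative is exposed.

Two post-processing modes exist:

* **phase-averaged** — the decomposition above over all N cycles;
* **instantaneous final cycle** — the conventional laminar-style analysis
  of the last cycle only. Turbulence statistics are undefined here, and
  requesting them raises an error *before* any computation. With a single
  cycle (N = 1) the RMS operators return zeros with a warning rather than
  failing, so final-cycle datasets flow through the same pipeline.

A convergence-in-N diagnostic (relative RMS change in ⟨φ⟩ when the last
cycle is added) is provided because the choice N = 30 is conventionally
justified by periodicity of outlet pressure rather than of every
statistic; no threshold is asserted — users decide per quantity.

## Wall shear stress family

WSS is the wall-tangential traction τ_wall = μ ∂u/∂n, evaluated from a
one-sided derivative of the near-wall velocity along the inward normal:
with the no-slip zero at the wall and samples at one offset the derivative
is the two-point slope; with two offsets it is the one-sided second-order
(quadratic-fit) derivative. The wall-normal traction component is
discarded. No wall-function model is provided — the intended inputs are
wall-resolved meshes.

* **TAWSS** is the cycle-time average of |⟨τ_wall⟩| — the magnitude of the
  phase-mean vector. The average-of-magnitudes alternative ⟨|τ_wall|⟩ is
  available (`tawss_of_magnitude_mean`) but is not the default: averaging
  the vector first is the conventional TAWSS and is the quantity OSI is
  defined against.
* **Turbulent WSS** is the per-phase RMS over cycles of the *vector*
  deviation norm ‖τ − ⟨τ⟩‖ (consistent with TKE's sum over components).
  The scalar alternative — RMS of the magnitude deviation — is exposed via
  `method="magnitude"`.
* **OSI** = 0.5 (1 − ‖∫⟨τ⟩dt‖ / ∫‖⟨τ⟩‖dt), both integrals by the periodic
  trapezoid. The triangle inequality on the quadrature sums bounds OSI to
  [0, 0.5] for any input; faces with a vanishing magnitude integral (no
  flow) return 0 by convention. In final-cycle mode the instantaneous WSS
  series substitutes for ⟨τ⟩.

## Volume statistics

* **TKE** = (ρ/2) Σᵢ ⟨uᵢ′⟩², an energy density reported in Pa.
* **Viscous dissipation rate** integrates (μ/2) Σᵢⱼ (∂uᵢ/∂xⱼ + ∂uⱼ/∂xᵢ)²
  over the vessel volume (W); applied to the phase-mean field it gives the
  laminar loss rate, and its cycle integral the net loss per cycle (J).
* **Turbulent dissipation rate** applies the same functional to the
  fluctuating field u′ = u − ⟨u⟩ **per cycle, then phase-averages the
  result over cycles**. The alternative reading — differentiating the RMS
  field itself — is not a second-order statistic (it measures gradients of
  the envelope, not the mean-square fluctuation gradient) and is exposed
  only as a clearly labelled non-default (`method="rms_gradient"`).

Gradients are evaluated on structured curvilinear blocks by central
differences in logical space (periodic across the azimuthal seam,
one-sided second order at block boundaries) combined through the inverse
coordinate Jacobian, so tensors are expressed in the global Cartesian
frame. The scheme is exact on affine fields and second-order on smooth
ones. **Unstructured meshes are not differentiated internally**: callers
must supply solver-exported gradients, because any internal least-squares
reconstruction would silently add a second discretisation on top of the
solver's. Volume integrals use cell-centroid values × cell volume;
node-sampled fields are first averaged to cell corners' mean.

For these integrals the instantaneous dissipation (per-cycle fields)
always exceeds the dissipation of the phase-mean field, the gap being the
turbulent part up to a cross term that vanishes in expectation — this is
the mechanism by which final-cycle-only post-processing overpredicts
viscous energy loss.

## ROI analysis

Regions are named segments with every element assigned to exactly one
region (or excluded). Because anatomical splits are drawn manually in
practice, the built-in generator is a surrogate: axial/centreline binning
at user-given cut positions, with the four aortic names (AAo, arch,
proximal DAo, distal DAo) as the default labels for four bins.
User-supplied label maps are accepted for real anatomies. Spatial averages
are volume-weighted for volumetric quantities and area-weighted for wall
quantities — the only convention consistent with "spatially integrated"
reporting — and the whole-domain row always equals the weight-combined
regional rows to 1e-10 relative.

## Comparison and resolution diagnostics

* **Voxel downsampling** emulates the voxel-integrating physics of phase-
  contrast MRI: the volume-weighted mean of all samples whose centroid
  falls in a voxel; empty voxels are NaN-masked. Nearest-neighbour
  interpolation was rejected as it under-represents intravoxel averaging.
* **Pearson R** is computed point-by-point per velocity component over the
  shared unmasked voxels, with the conventional bands R > 0.7 high and
  R > 0.5 moderate. Zero-variance components raise rather than return 0.
* **Two-point correlation** B(r) of fluctuations along a grid line is the
  normalised autocorrelation at separations r = 0, h, 2h, …; the
  resolved-cell count is the distance to the first zero crossing of B in
  units of h (linearly interpolated), with ≥ 8 cells per largest scale
  flagged adequate. If B never crosses zero on the line the count is the
  line length, flagged as a lower bound. The line mean is removed by
  default; note a demeaned line always decorrelates somewhere, so the
  lower-bound branch only arises for externally demeaned input
  (`demean=False`).

## Synthetic data generator

The generator emulates the *statistical structure* of patient CFD output,
not its physics:

* **Mean flow** — the analytic Womersley solution in a rigid straight pipe
  of radius R = 12 mm and length 100 mm (aortic calibre): a Poiseuille
  component for the waveform mean plus, per harmonic k of the bulk
  velocity waveform, the Bessel profile with Womersley number
  αₖ = R √(kωρ/μ), normalised so the cross-section average reproduces the
  prescribed waveform exactly. Fluid properties default to blood-like
  ρ = 1060 kg/m³, μ = 0.0035 Pa·s. The default waveform (mean 0.12 m/s +
  two harmonics, peak bulk velocity ≈ 0.43 m/s at t ≈ 0.2 T, T = 1 s)
  gives α₁ ≈ 16 — physiological for the human aorta.
* **Disturbances** — zero-mean Gaussian random fields, independent across
  cycles, smoothed (with periodic wrap, so the pointwise variance is
  stationary and exactly normalisable) to a 2 mm correlation length,
  scaled by an envelope σ(t) that is a Gaussian bump peaking at 0.3 T with
  width 0.08 T and amplitude 0.05 m/s — fluctuation energy concentrated in
  systolic deceleration, the phase where turbulence production peaks in
  stenotic aortic flow. Fluctuations are windowed by 1 − (r/R)² so the
  wall remains exactly no-slip. They satisfy no momentum equation and
  carry no realistic spectra or anisotropy; what passing recovery tests
  demonstrate is that the *statistics pipeline* is correct, not that the
  generator resembles turbulence.
* **Geometry** — a structured cylindrical block (default 32 × 24 × 64 in
  r, θ, z; M = 50 phases, N = 30 cycles, matching the multi-cycle study
  design the pipeline targets). A small axis core (2 % of R) is excluded
  because the curvilinear Jacobian is singular on the axis; the
  dissipation density scales as r² there, so the truncation error is
  O((r₀/R)⁴) ≈ 3 × 10⁻⁷ relative. Optional geometric radial stretching
  (ratio q < 1 toward the wall) refines the near-wall spacing; the
  wall-shear validation uses 48 radial points with q = 0.85, at which the
  computed per-phase WSS matches the analytic Womersley shear to well
  under 1 % RMS. Near-wall velocity is sampled at the two outermost
  interior radial node rings, so the WSS offsets equal the last two radial
  spacings.
* **MRI-like companion** — the voxel-averaged mean field at 20 uniform
  phases on a 2.5 mm isotropic voxel grid (typical 4D-flow resolution),
  with optional additive Gaussian noise; all randomness, including this
  noise, derives from the single dataset seed, and identical spec + seed
  reproduce datasets bit for bit.

## Numerical choices and degenerate inputs

* Exact zeros are enforced where the model guarantees them (no-slip at
  r = R), since Bessel evaluation leaves ~1e-16 residue.
* OSI clips rounding residue into [0, 0.5]; zero-denominator faces → 0.
* N = 1 ensembles: RMS-type quantities return zeros + warning, not errors.
* Empty ROI bins and zero-variance correlation components raise
  descriptive errors naming the offending label/component.
* Identical-cycle ensembles reproduce their cycle to reduction rounding
  (~1e-16 relative); tests and the pipeline treat ≤ 1e-12 as zero.

## Problem sizes

Validation cases are sized for a single CPU: the recovery check runs the
full default ensemble (30 × 50 phases on 32 × 24 × 64, ≈ 1.8 GB); the
Poiseuille dissipation check uses 64 × 32 × 16 cells (quadrature error
< 1 %, dominated by the polygonal approximation of the circular section);
the finite-difference Womersley oracle integrates 25 periods of a
Crank–Nicolson scheme on 300 radial points so the homogeneous transient
(decay time ≈ 2.75 periods at α = 10) is negligible.

## Known limitations

* Straight rigid axisymmetric geometry only in the generator: no valve
  jet, curvature, branches or wall motion; ROI splits on real anatomies
  must be supplied as label maps.
* Gradient evaluation requires a structured block or solver-supplied
  tensors.
* The fluctuation model has controllable two-point structure but is not
  divergence-free and has no energy cascade; turbulence-model questions
  (e.g. subgrid-scale contributions) are out of scope.
* File formats are HDF5/CSV/JSON; VTK interchange is not implemented.
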