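"""Wall shear stress family: WSS from near-wall velocity, TAWSS, OSI,
turbulent WSS — against analytic and hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from hemophase import (
    FluidProperties,
    SyntheticSpec,
    TimeGrid,
    WallSurface,
    generate_ensemble,
    osi,
    surface_average,
    tawss,
    tawss_of_magnitude_mean,
    turbulent_tawss,
    turbulent_wss,
    wss_from_near_wall_velocity,
)

FLUID = FluidProperties()


def _flat_wall(n_faces=1, offsets=(1e-4, 2e-4)):
    return WallSurface(
        face_centres=np.zeros((n_faces, 3)),
        unit_normals=np.tile([0.0, 1.0, 0.0], (n_faces, 1)),
        face_areas=np.ones(n_faces),
        adjacent_sample_offsets=np.array(offsets),
    )


# ------------------------------------------------- WSS from near-wall velocity

def test_linear_shear_wss():
    # u_t = k d with k = 100 1/s: |tau| = mu k = 0.35 Pa exactly
    wall = _flat_wall()
    k = 100.0
    u = np.zeros((1, 1, 1, 2, 3))
    u[..., 0, 0] = k * wall.adjacent_sample_offsets[0]
    u[..., 1, 0] = k * wall.adjacent_sample_offsets[1]
    tau = wss_from_near_wall_velocity(u, wall, FLUID)
    assert np.linalg.norm(tau[0, 0, 0]) == pytest.approx(0.35, rel=1e-12)


def test_zero_flow_gives_zero_wss():
    wall = _flat_wall(n_faces=4)
    u = np.zeros((2, 3, 4, 2, 3))
    assert np.max(np.abs(wss_from_near_wall_velocity(u, wall, FLUID))) == 0.0


def test_normal_component_is_discarded():
    wall = _flat_wall()
    u = np.zeros((1, 1, 1, 2, 3))
    u[..., :, 1] = 1.0  # purely wall-normal velocity
    tau = wss_from_near_wall_velocity(u, wall, FLUID)
    assert np.max(np.abs(tau)) < 1e-15


def test_single_offset_first_order_derivative():
    wall = _flat_wall(offsets=(2e-4,))
    u = np.zeros((1, 1, 1, 1, 3))
    u[..., 0, 2] = 0.02
    tau = wss_from_near_wall_velocity(u, wall, FLUID)
    assert tau[0, 0, 0, 2] == pytest.approx(FLUID.dynamic_viscosity * 100.0)


def test_poiseuille_wall_shear():
    # steady pipe: |tau_wall| = 4 mu U / R = 0.14 Pa within 1%
    spec = SyntheticSpec(
        grid=(64, 12, 6), radius=0.01, waveform_mean=0.1, harmonics=(),
        sigma_peak=0.0, n_phases=4, n_cycles=1,
    )
    ds = generate_ensemble(spec, include_mri=False)
    tau = wss_from_near_wall_velocity(ds.near_wall, ds.wall, spec.fluid)
    mags = np.linalg.norm(tau[0, 0], axis=-1)
    assert surface_average(mags, ds.wall) == pytest.approx(0.14, rel=0.01)


def test_womersley_wall_shear_within_2pct_rms():
    # pulsatile pipe at refined radial resolution: per-phase WSS within 2% RMS
    spec = SyntheticSpec(
        grid=(48, 12, 8), n_phases=50, n_cycles=1, sigma_peak=0.0,
        radial_stretch=0.85,
    )
    ds = generate_ensemble(spec, include_mri=False)
    tau = wss_from_near_wall_velocity(ds.near_wall, ds.wall, spec.fluid)
    computed = tau[0, :, :, 2].mean(axis=1)  # axial component, surface mean
    analytic = ds.truth.wall_shear
    err = np.sqrt(np.mean((computed - analytic) ** 2))
    scale = np.sqrt(np.mean(analytic**2))
    assert err / scale < 0.02


# ----------------------------------------------------------------- TAWSS

def test_tawss_constant_vector():
    grid = TimeGrid.uniform(1.0, 8, 1)
    tau = np.zeros((8, 3, 3))
    tau[..., 0] = 2.0
    assert tawss(tau, grid) == pytest.approx(np.full(3, 2.0))


def test_tawss_abs_sin_closed_form():
    # |<tau>|(t) = |sin(2 pi t / T)|: time average 2/pi
    grid = TimeGrid.uniform(1.0, 400, 1)
    tau = np.zeros((400, 1, 3))
    tau[:, 0, 0] = np.sin(2 * np.pi * grid.phase_times)
    assert tawss(tau, grid)[0] == pytest.approx(2 / np.pi, abs=1e-4)


def test_tawss_magnitude_mean_alternative(rng):
    # for a sign-reversing ensemble <|tau|> time average exceeds |<tau>|'s
    grid = TimeGrid.uniform(1.0, 16, 2)
    tau = rng.normal(size=(2, 16, 5, 3))
    tau[1] = -tau[0]  # phase mean is zero
    assert np.all(tawss(tau.mean(axis=0), grid) < 1e-12)
    assert np.all(tawss_of_magnitude_mean(tau, grid) > 0)


# -------------------------------------------------------------- turbulent WSS

def test_turbulent_wss_zero_for_identical_cycles(rng):
    tau1 = rng.normal(size=(1, 4, 6, 3))
    tau = np.repeat(tau1, 5, axis=0)
    turb = turbulent_wss(tau, tau.mean(axis=0))
    assert np.max(turb) < 1e-14
    grid = TimeGrid.uniform(1.0, 4, 5)
    assert np.max(turbulent_tawss(turb, grid)) < 1e-14


def test_turbulent_wss_fixed_norm_deviation():
    # deviations of norm b at fixed phase -> RMS exactly b
    b = 0.4
    base = np.zeros((1, 2, 1, 3))
    dev = np.zeros((4, 2, 1, 3))
    dev[0, :, 0, 0] = b
    dev[1, :, 0, 0] = -b
    dev[2, :, 0, 1] = b
    dev[3, :, 0, 1] = -b
    tau = base + dev
    turb = turbulent_wss(tau, tau.mean(axis=0))
    assert turb == pytest.approx(np.full((2, 1), b), rel=1e-12)


def test_turbulent_wss_gaussian_noise_sqrt3_sigma(rng):
    # isotropic Gaussian vector noise sigma per component: RMS deviation
    # magnitude sqrt(3) sigma (times the sqrt(1 - 1/N) sample-mean factor)
    n, sigma, faces = 30, 0.2, 3000
    tau = rng.normal(0.0, sigma, size=(n, 2, faces, 3))
    turb = turbulent_wss(tau, tau.mean(axis=0))
    expected = np.sqrt(3) * sigma * np.sqrt(1 - 1 / n)
    assert np.sqrt((turb**2).mean()) == pytest.approx(expected, rel=0.02)


def test_turbulent_wss_matches_brute_force(rng):
    tau = rng.normal(size=(5, 3, 10, 3))
    mean = tau.mean(axis=0)
    brute = np.zeros((3, 10))
    for m in range(3):
        for f in range(10):
            acc = 0.0
            for n in range(5):
                acc += np.sum((tau[n, m, f] - mean[m, f]) ** 2)
            brute[m, f] = np.sqrt(acc / 5)
    assert np.max(np.abs(turbulent_wss(tau, mean) - brute)) < 1e-12


def test_turbulent_wss_magnitude_method(rng):
    tau = rng.normal(size=(6, 2, 4, 3))
    mean = tau.mean(axis=0)
    turb = turbulent_wss(tau, mean, method="magnitude")
    mags = np.linalg.norm(tau, axis=-1)
    brute = np.sqrt(((mags - mags.mean(axis=0)) ** 2).mean(axis=0))
    assert np.allclose(turb, brute, atol=1e-12)
    with pytest.raises(ValueError):
        turbulent_wss(tau, mean, method="nope")


# -------------------------------------------------------------------- OSI

def test_osi_constant_direction_is_zero():
    grid = TimeGrid.uniform(1.0, 400, 1)
    tau = np.zeros((400, 1, 3))
    tau[:, 0, 0] = 1.0 + 0.5 * np.sin(2 * np.pi * grid.phase_times)
    assert osi(tau, grid)[0] == pytest.approx(0.0, abs=1e-10)


def test_osi_zero_mean_sinusoid_is_half():
    grid = TimeGrid.uniform(1.0, 400, 1)
    tau = np.zeros((400, 1, 3))
    tau[:, 0, 0] = 2.0 * np.sin(2 * np.pi * grid.phase_times)
    assert osi(tau, grid)[0] == pytest.approx(0.5, abs=1e-10)


def test_osi_offset_sinusoid_quadrature_oracle():
    # tau_x = 1 + 2 sin(2 pi t / T): OSI = 0.5 (1 - 2 pi / int |1 + 2 sin|)
    grid = TimeGrid.uniform(1.0, 400, 1)
    tau = np.zeros((400, 1, 3))
    tau[:, 0, 0] = 1.0 + 2.0 * np.sin(2 * np.pi * grid.phase_times)
    integral = quad(lambda th: abs(1 + 2 * np.sin(th)), 0, 2 * np.pi)[0]
    oracle = 0.5 * (1 - 2 * np.pi / integral)
    assert osi(tau, grid)[0] == pytest.approx(oracle, abs=1e-4)


def test_osi_zero_for_no_flow():
    grid = TimeGrid.uniform(1.0, 8, 1)
    assert osi(np.zeros((8, 2, 3)), grid) == pytest.approx(np.zeros(2))


@settings(derandomize=True, max_examples=50)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_osi_bounded_for_any_series(seed):
    rng = np.random.default_rng(seed)
    grid = TimeGrid.uniform(1.0, 12, 1)
    tau = rng.normal(size=(12, 7, 3)) * rng.lognormal(size=(12, 7, 1))
    vals = osi(tau, grid)
    assert np.all(vals >= 0.0) and np.all(vals <= 0.5)


def test_tawss_and_osi_rotation_invariant(rng):
    grid = TimeGrid.uniform(1.0, 24, 1)
    tau = rng.normal(size=(24, 9, 3))
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    tau_rot = tau @ rot.T
    assert np.allclose(tawss(tau, grid), tawss(tau_rot, grid), rtol=1e-12)
    assert np.allclose(osi(tau, grid), osi(tau_rot, grid), rtol=1e-10, atol=1e-12)


def test_velocity_scaling_property(rng):
    # scaling velocities by lambda scales WSS/TAWSS by lambda, OSI unchanged
    lam = 3.7
    wall = _flat_wall(n_faces=5)
    grid = TimeGrid.uniform(1.0, 6, 4)
    u = rng.normal(size=(4, 6, 5, 2, 3))
    tau = wss_from_near_wall_velocity(u, wall, FLUID)
    tau_scaled = wss_from_near_wall_velocity(lam * u, wall, FLUID)
    assert np.allclose(tau_scaled, lam * tau, rtol=1e-12)
    mean, mean_s = tau.mean(axis=0), tau_scaled.mean(axis=0)
    assert np.allclose(tawss(mean_s, grid), lam * tawss(mean, grid), rtol=1e-12)
    assert np.allclose(osi(mean_s, grid), osi(mean, grid), rtol=1e-10)
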