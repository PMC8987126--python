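"""Discrete operators: gradients, cycle integrals, volume/surface integrals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemophase import (
    TimeGrid,
    UnsupportedMeshError,
    VolumeMesh,
    WallSurface,
    cycle_integral,
    gradient_tensor,
    structured_block_mesh,
    surface_average,
    volume_integral,
)
from hemophase.synthetic_data import SyntheticSpec, cylinder_mesh


# ---------------------------------------------------------------- time grid

def test_time_grid_validation():
    with pytest.raises(ValueError):
        TimeGrid(period=1.0, phase_times=np.array([0.0, 0.5, 0.4]), n_cycles=1)
    with pytest.raises(ValueError):
        TimeGrid(period=1.0, phase_times=np.array([0.0, 1.0]), n_cycles=1)
    with pytest.raises(ValueError):
        TimeGrid.uniform(1.0, 1, 1)
    with pytest.raises(ValueError):
        TimeGrid.uniform(1.0, 4, 0)


@pytest.mark.parametrize(
    "series_fn, expected, tol",
    [
        (lambda t: np.full_like(t, 3.0), 3.0 * 1.0, 1e-14),          # constant
        (lambda t: np.sin(2 * np.pi * t) ** 2, 0.5, 1e-6),           # closed form
    ],
)
def test_cycle_integral_closed_forms(series_fn, expected, tol):
    grid = TimeGrid.uniform(1.0, 200, 1)
    val = cycle_integral(series_fn(grid.phase_times), grid)
    assert val == pytest.approx(expected, rel=tol)


def test_cycle_integral_matches_hand_trapezoid_on_ramp():
    # ramp 0, 1, 2, 3 at t = 0, .25, .5, .75 closing periodically back to 0 at T=1
    grid = TimeGrid.uniform(1.0, 4, 1)
    series = np.array([0.0, 1.0, 2.0, 3.0])
    hand = 0.25 * (0.5 * (0 + 1) + 0.5 * (1 + 2) + 0.5 * (2 + 3) + 0.5 * (3 + 0))
    assert cycle_integral(series, grid) == pytest.approx(hand, abs=1e-15)


@settings(derandomize=True, max_examples=25)
@given(
    m=st.integers(min_value=2, max_value=40),
    scale=st.floats(min_value=0.1, max_value=10.0),
)
def test_cycle_integral_equals_period_times_mean_on_uniform_grid(m, scale):
    grid = TimeGrid.uniform(0.8, m, 1)
    rng = np.random.default_rng(m)
    series = rng.normal(0, scale, size=m)
    assert cycle_integral(series, grid) == pytest.approx(
        0.8 * series.mean(), rel=1e-12, abs=1e-12
    )


# ----------------------------------------------------------------- gradient

def test_gradient_exact_on_affine_field(box_mesh, rng):
    a = rng.normal(size=(3, 3))
    b = rng.normal(size=3)
    u = box_mesh.node_coordinates @ a.T + b
    grad = gradient_tensor(box_mesh, u)
    assert np.max(np.abs(grad - a)) < 1e-12


def test_gradient_exact_on_affine_field_curvilinear(rng):
    # affine exactness must also hold on a curved (cylindrical) block
    mesh = cylinder_mesh(SyntheticSpec(grid=(8, 10, 6)))
    a = rng.normal(size=(3, 3))
    u = mesh.node_coordinates @ a.T
    grad = gradient_tensor(mesh, u)
    assert np.max(np.abs(grad - a)) < 1e-11


def test_gradient_zero_for_uniform_field(box_mesh):
    u = np.tile([1.0, -2.0, 0.5], (box_mesh.n_nodes, 1))
    assert np.max(np.abs(gradient_tensor(box_mesh, u))) < 1e-13


def test_gradient_poiseuille_wall_derivative():
    # u_z(r) = 2U(1 - r^2/R^2): du_z/dr at r = R equals -4U/R
    u_mean, radius = 0.1, 0.01
    spec = SyntheticSpec(
        grid=(64, 12, 6), radius=radius, waveform_mean=u_mean, harmonics=()
    )
    mesh = cylinder_mesh(spec)
    r = np.linalg.norm(mesh.node_coordinates[:, :2], axis=1)
    u = np.zeros((mesh.n_nodes, 3))
    u[:, 2] = 2 * u_mean * (1 - (r / radius) ** 2)
    grad = gradient_tensor(mesh, u)
    # radial derivative of u_z at the wall nodes
    wall = r > radius * (1 - 1e-9)
    er = mesh.node_coordinates[:, :2] / r[:, None]
    dudr = grad[:, 2, 0] * er[:, 0] + grad[:, 2, 1] * er[:, 1]
    assert dudr[wall] == pytest.approx(-4 * u_mean / radius, rel=1e-3)


def test_gradient_second_order_convergence():
    # smooth field on a cylindrical block; refine 3 times, slope >= 1.9
    errs, hs = [], []
    for factor in (1, 2, 4):
        spec = SyntheticSpec(grid=(8 * factor, 8 * factor, 8 * factor))
        mesh = cylinder_mesh(spec)
        xyz = mesh.node_coordinates / spec.radius
        u = np.stack(
            [
                np.sin(xyz[:, 0]) * np.cos(xyz[:, 1]),
                np.cos(xyz[:, 2]) * xyz[:, 0],
                np.sin(xyz[:, 1] + 0.3 * xyz[:, 2]),
            ],
            axis=-1,
        )
        exact = np.zeros((mesh.n_nodes, 3, 3))
        exact[:, 0, 0] = np.cos(xyz[:, 0]) * np.cos(xyz[:, 1])
        exact[:, 0, 1] = -np.sin(xyz[:, 0]) * np.sin(xyz[:, 1])
        exact[:, 1, 0] = np.cos(xyz[:, 2])
        exact[:, 1, 2] = -np.sin(xyz[:, 2]) * xyz[:, 0]
        exact[:, 2, 1] = np.cos(xyz[:, 1] + 0.3 * xyz[:, 2])
        exact[:, 2, 2] = 0.3 * np.cos(xyz[:, 1] + 0.3 * xyz[:, 2])
        exact /= spec.radius
        grad = gradient_tensor(mesh, u)
        errs.append(np.sqrt(np.mean((grad - exact) ** 2)))
        hs.append(1.0 / factor)
    slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
    assert slope >= 1.9


def test_gradient_rejects_unstructured_mesh(box_mesh):
    mesh = VolumeMesh(
        node_coordinates=box_mesh.node_coordinates,
        cell_connectivity=box_mesh.cell_connectivity,
        cell_volumes=box_mesh.cell_volumes,
        cell_centroids=box_mesh.cell_centroids,
        structured_shape=None,
    )
    u = np.zeros((mesh.n_nodes, 3))
    with pytest.raises(UnsupportedMeshError, match="structured"):
        gradient_tensor(mesh, u)


# ---------------------------------------------------------------- integrals

def test_volume_integral_indicator_gives_total_volume(box_mesh):
    ones = np.ones(box_mesh.n_cells)
    assert volume_integral(ones, box_mesh) == pytest.approx(
        box_mesh.total_volume, rel=1e-12
    )
    # the box mesh covers the unit cube
    assert box_mesh.total_volume == pytest.approx(1.0, rel=1e-12)


def test_volume_integral_hand_arithmetic():
    mesh = _two_cell_mesh(volumes=(1.0, 3.0))
    values = np.array([4.0, 0.0])
    assert volume_integral(values, mesh) == pytest.approx(4.0)
    mean = volume_integral(values, mesh) / mesh.total_volume
    assert mean == pytest.approx(1.0)


def test_volume_integral_additive_over_partition(box_mesh, rng):
    values = rng.normal(size=box_mesh.n_cells)
    total = volume_integral(values, box_mesh)
    split = rng.random(box_mesh.n_cells) < 0.4
    part = values.copy()
    part[~split] = 0.0
    rest = values.copy()
    rest[split] = 0.0
    assert volume_integral(part, box_mesh) + volume_integral(rest, box_mesh) == (
        pytest.approx(total, rel=1e-12)
    )


def test_volume_integral_shape_mismatch(box_mesh):
    with pytest.raises(ValueError):
        volume_integral(np.ones(box_mesh.n_cells + 1), box_mesh)


def test_surface_average_constant_and_weights():
    wall = WallSurface(
        face_centres=np.zeros((3, 3)),
        unit_normals=np.tile([1.0, 0.0, 0.0], (3, 1)),
        face_areas=np.array([1.0, 2.0, 1.0]),
        adjacent_sample_offsets=np.array([1e-4]),
    )
    assert surface_average(np.full(3, 7.0), wall) == pytest.approx(7.0)
    assert surface_average(np.array([0.0, 1.0, 0.0]), wall) == pytest.approx(0.5)


def test_wall_surface_rejects_bad_normals():
    with pytest.raises(ValueError, match="unit"):
        WallSurface(
            face_centres=np.zeros((1, 3)),
            unit_normals=np.array([[1.0, 1.0, 0.0]]),
            face_areas=np.array([1.0]),
            adjacent_sample_offsets=np.array([1e-4]),
        )


def _two_cell_mesh(volumes):
    # degenerate bookkeeping mesh: geometry unused by the integral
    nodes = np.zeros((8, 3))
    conn = np.tile(np.arange(8), (2, 1))
    return VolumeMesh(
        node_coordinates=nodes,
        cell_connectivity=conn,
        cell_volumes=np.asarray(volumes, dtype=float),
        cell_centroids=np.zeros((2, 3)),
    )
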