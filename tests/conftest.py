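import numpy as np
import pytest

from hemophase import (
    CycleEnsemble,
    SyntheticSpec,
    TimeGrid,
    generate_ensemble,
    structured_block_mesh,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_spec():
    """Small disturbed-flow dataset spec reused across tests."""
    return SyntheticSpec(grid=(16, 12, 24), n_phases=20, n_cycles=8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_ensemble(small_spec, include_mri=False)


@pytest.fixture(scope="session")
def laminar_spec(small_spec):
    from dataclasses import replace

    return replace(small_spec, sigma_peak=0.0)


@pytest.fixture(scope="session")
def laminar_dataset(laminar_spec):
    return generate_ensemble(laminar_spec, include_mri=False)


@pytest.fixture
def box_mesh():
    """Uniform Cartesian 8x9x10 block on [0,1]^3 (non-periodic)."""
    x = np.linspace(0.0, 1.0, 8)
    y = np.linspace(0.0, 1.0, 9)
    z = np.linspace(0.0, 1.0, 10)
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    return structured_block_mesh(np.stack([xx, yy, zz], axis=-1))


def toy_ensemble(rng, n_cycles=5, n_phases=3, n_locations=10, n_components=3,
                 period=0.8):
    grid = TimeGrid.uniform(period, n_phases, n_cycles)
    values = rng.normal(0.0, 1.0, size=(n_cycles, n_phases, n_locations, n_components))
    return CycleEnsemble(time_grid=grid, values=values, units="m/s", name="toy")
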