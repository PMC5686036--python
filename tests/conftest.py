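import numpy as np
import pytest

from fivedpet import (
    PhantomConfig,
    VoxelGrid,
    make_basis_set,
    simulate_input_functions,
    water_protocol_schedule,
)


def small_phantom_config(**overrides) -> PhantomConfig:
    """A fast desk-scale phantom: 40x40x24 grid of 5-mm voxels, ~69/27 mL cavity."""
    kwargs = dict(
        grid=VoxelGrid((40, 40, 24), (5.0, 5.0, 5.0)),
        lv_semi_axes_ed_mm=(22.0, 22.0, 34.0),
        lv_semi_axes_es_mm=(16.0, 16.0, 25.0),
        wall_thickness_ed_mm=8.0,
        wall_thickness_es_mm=11.0,
        lv_centre_offset_mm=(22.0, 0.0, 0.0),
        rv_offset_mm=(-52.0, 0.0, 0.0),
        rv_semi_axes_mm=(16.0, 22.0, 28.0),
        noise_scale=0.0,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def schedule():
    return water_protocol_schedule()


@pytest.fixture(scope="session")
def inputs(schedule):
    return simulate_input_functions(PhantomConfig())


@pytest.fixture(scope="session")
def basis(inputs, schedule):
    return make_basis_set(inputs, schedule)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free blurred small phantom shared across tests."""
    from fivedpet import generate_phantom

    cfg = small_phantom_config()
    series, truth = generate_phantom(cfg)
    return series, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231114)
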