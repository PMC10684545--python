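import numpy as np
import pytest

from phasestain.simulate import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """A 256-px scene with two aggregates, shared across read-only tests."""
    return generate_scene(SceneSpec(seed=42))


@pytest.fixture(scope="session")
def weak_phase_spec():
    """Scene recipe in the weak-phase regime (max phase ~0.3 rad)."""
    return SceneSpec(
        field_size_px=(256, 256),
        n_cells=3,
        cell_phase_range_rad=(0.04, 0.10),
        n_aggregates=2,
        aggregate_area_range_um2=(3.0, 12.0),
        aggregate_phase_range_rad=(0.15, 0.28),
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
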