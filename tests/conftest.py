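import numpy as np
import pytest

from nichechart.stack_io import ImageStack
from nichechart.synthetic import fed_preset, starved_preset, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_stack(rng):
    """Small random 3-channel stack factory."""

    def make(shape=(10, 8, 8, 3), scale=100.0, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return ImageStack(
            voxels=r.uniform(0.0, scale, size=shape),
            channel_roles={"glia": 0, "nsc": 1, "neuron": 2},
            specimen_id="rand",
        )

    return make


@pytest.fixture(scope="session")
def fed_scene():
    """One fed-preset scene at a compact shape, with ground truth."""
    config = fed_preset((30, 96, 96), seed=11)
    stack, truth = generate_scene(config)
    return stack, truth, config


@pytest.fixture(scope="session")
def starved_scene():
    config = starved_preset((30, 96, 96), seed=12)
    stack, truth = generate_scene(config)
    return stack, truth, config
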