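import numpy as np
import pytest

from spikecount.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One modest N4 scene with disjoint spikes, shared across tests."""
    config = SceneConfig(
        image_height=486,
        image_width=648,
        n_spikes=8,
        n_leaves=12,
        overlap_probability=0.0,
        nitrogen_like="N4",
        seed=11,
    )
    image, truth = generate_scene(config)
    return config, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
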