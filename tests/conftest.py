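import numpy as np
import pytest

from ricianet import NetworkConfig, PhantomConfig, generate_phantom


def random_config(rng):
    """A random valid architecture, for shape-contract sweeps."""
    n_layers = int(rng.integers(3, 7))
    candidates = list(range(3, n_layers + 1))
    k = int(rng.integers(0, len(candidates) + 1))
    positions = frozenset(rng.choice(candidates, size=k, replace=False).tolist()) or None
    return NetworkConfig(
        base_channels=int(rng.integers(2, 9)),
        n_extraction_layers=n_layers,
        dilation_rate=int(rng.integers(1, 4)),
        dilated_layer_positions=positions,
        spatial_attention_pooling=["max_extra", "avg_extra"][int(rng.integers(2))],
        spatial_attention_kernel=[3, 5, 7][int(rng.integers(3))],
        fusion_layers=int(rng.integers(1, 3)),
        channel_attention_reduction=int(rng.integers(1, 5)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom_config():
    """A small slice so CPU tests stay fast."""
    return PhantomConfig(height=48, width=40, n_tissue_regions=2, seed=7)


@pytest.fixture
def small_phantom(small_phantom_config):
    return generate_phantom(small_phantom_config)


@pytest.fixture
def micro_net_config():
    """Smallest valid architecture, used for gradient checks and shape tests."""
    return NetworkConfig(
        base_channels=4,
        n_extraction_layers=3,
        fusion_layers=2,
        spatial_attention_kernel=3,
        dilated_layer_positions=frozenset({3}),
        channel_attention_reduction=2,
    )
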