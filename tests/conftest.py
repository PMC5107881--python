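import numpy as np
import pytest
from hypothesis import settings

from nirscnn import NoiseSpec, SimulationConfig, TaskSchedule
from nirscnn.cnn import CNNConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_cnn_config():
    """Small instance used for oracle and gradient checks (N=12, K=2, m=3)."""
    return CNNConfig(kernel_len=3, n_kernels=2, pool_len=2, pool_stride=2,
                     epochs=5)


@pytest.fixture
def short_schedule():
    """Compressed block design for fast simulation tests."""
    return TaskSchedule(pre_rest_s=10, n_trials=6, memorize_s=3, retain_s=1,
                        respond_s=7, post_rest_s=10)


@pytest.fixture
def small_sim_config(short_schedule):
    """Few channels, short session, effect planted on CH2."""
    return SimulationConfig(
        n_per_group=3,
        n_channels=4,
        schedule=short_schedule,
        discriminative_channels=frozenset({2}),
        effect_amplitude=1.0,
        effect_window=(0.0, 1.0),  # whole task, so any feature window sees it
        seed=123,
    )


@pytest.fixture
def silent_noise():
    return NoiseSpec.silent()
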