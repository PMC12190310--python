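import numpy as np
import pytest

from mmdda.encoder3d import EncoderConfig
from mmdda.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_encoder() -> EncoderConfig:
    """Two-layer encoder for 16^3 volumes: 16->14->7 (pool) ->5->2 (pool)."""
    return EncoderConfig(channels=(4, 8), pool_after=frozenset({1, 2}))


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return SyntheticConfig(volume_shape=(16, 16, 16), n_per_class_source=4,
                           n_per_class_target=4, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f() with respect to array x
    (f must read x in place)."""
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        f_plus = f()
        x[idx] = orig - eps
        f_minus = f()
        x[idx] = orig
        grad[idx] = (f_plus - f_minus) / (2 * eps)
    return grad
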