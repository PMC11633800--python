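import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def feature_benchmark():
    """Feature-space recovery benchmark (trains 5 restarts; ~30 s, shared)."""
    from ramil.benchmark import run_feature_benchmark

    return run_feature_benchmark(base_seed=0, n_seeds=5)


@pytest.fixture(scope="session")
def image_benchmark():
    """Image localization benchmark (encoding dominates; ~1 min, shared)."""
    from ramil.benchmark import run_image_benchmark

    return run_image_benchmark(seed=0)
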