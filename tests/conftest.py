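import numpy as np
import pytest

from smoothpls.synthetic import SyntheticConfig, gen_feature_tensor, gen_trajectory


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small noiseless-ish planted-factor dataset (tensor, trajectory)."""
    cfg = SyntheticConfig(n_epochs=120, dims=(5, 4, 6), n_factors=2,
                          snr=10.0, noise_ar=0.2)
    traj = gen_trajectory(cfg, 7)
    tensor = gen_feature_tensor(traj, cfg, 8)
    return tensor, traj, cfg


@pytest.fixture(scope="session")
def random_pair():
    """Unstructured random tensor/response pair for algebraic checks."""
    local = np.random.default_rng(2024)
    X = local.standard_normal((60, 5, 4, 3))
    Y = local.standard_normal((60, 3))
    return X, Y
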