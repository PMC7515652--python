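import numpy as np
import pytest

from unbindkit.toy_dynamics import MixtureSurface


@pytest.fixture(scope="session")
def double_well():
    """Symmetric 1-D double well with a barrier of ~8 kT."""
    return MixtureSurface.double_well_1d(separation=2.0, sigma=0.24, beta=1.0)


@pytest.fixture(scope="session")
def asym_2d_surface():
    """Asymmetric two-Gaussian 2-D surface with correlated covariances."""
    return MixtureSurface(
        [
            (0.6, [-1.0, -0.3], [[0.25, 0.05], [0.05, 0.15]]),
            (0.4, [1.1, 0.4], [[0.12, -0.03], [-0.03, 0.3]]),
        ],
        beta=1.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_features():
    """15 channels: 3 independent smooth signals x 5 noisy copies each."""
    r = np.random.default_rng(7)
    n = 3000
    sig = r.standard_normal((3, n)).cumsum(axis=1) * 0.05
    sig = (sig - sig.mean(axis=1, keepdims=True)) / sig.std(axis=1, keepdims=True)
    cols, names = [], []
    for b in range(3):
        for c in range(5):
            cols.append(sig[b] + 0.1 * r.standard_normal(n))
            names.append(f"f{b+1}{c+1}")
    return np.array(cols).T, names
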