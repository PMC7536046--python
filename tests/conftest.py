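import numpy as np
import pytest
from scipy.signal import lfilter


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ar1_series(lam: float, n: int, seed: int, sigma: float = 1.0) -> np.ndarray:
    """Stationary AR(1) sample, x_{t+1} = lam x_t + sigma eps_t (burn-in discarded)."""
    rng = np.random.default_rng(seed)
    eps = sigma * rng.standard_normal(n + 500)
    return lfilter([1.0], [1.0, -lam], eps)[500:]


@pytest.fixture
def random_stable_specs():
    """A batch of randomized stable bifurcation specs covering every family."""
    from specews import BifurcationSpec

    rng = np.random.default_rng(7)
    specs = []
    for _ in range(4):
        specs.append(BifurcationSpec("fold", "continuous",
                                     lam=-rng.uniform(0.05, 3.0),
                                     sigma=rng.uniform(0.2, 2.0)))
        specs.append(BifurcationSpec("hopf", "continuous",
                                     mu=-rng.uniform(0.05, 1.0),
                                     omega0=rng.uniform(0.2, 2.0),
                                     sigma=rng.uniform(0.2, 2.0)))
        specs.append(BifurcationSpec("fold", "discrete",
                                     lam=rng.uniform(0.0, 0.95),
                                     sigma=rng.uniform(0.2, 2.0)))
        specs.append(BifurcationSpec("flip", "discrete",
                                     lam=-rng.uniform(0.0, 0.95),
                                     sigma=rng.uniform(0.2, 2.0)))
        specs.append(BifurcationSpec("neimark_sacker", "discrete",
                                     r_mod=rng.uniform(0.0, 0.95),
                                     theta=rng.uniform(0.3, 2.8),
                                     sigma=rng.uniform(0.2, 2.0)))
    return specs
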