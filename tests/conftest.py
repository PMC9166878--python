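import numpy as np
import pytest

import ciermix as cm


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with ground truth, shared across tests."""
    cfg = cm.SimConfig(N=120, S=2, J=(7, 5), seed=101, target_cier_rate=0.05)
    return cm.simulate_dataset(cfg)


@pytest.fixture
def toy_globals():
    """Global parameters for hand-checkable toy computations."""
    return cm.GlobalParams(
        beta_C=0.74, sigma_C=np.sqrt(0.78), sigma_A=0.5, gamma=0.04,
        kappa=np.array([0.14, 0.34, 0.41, 0.11]),
        Sigma=cm.default_sigma(2), K=3, S=2,
    )


@pytest.fixture
def toy_item():
    return cm.ItemParams("i1", "s1", v=1.3, b=np.array([-1.0, 0.2, 1.1]),
                         beta_star=0.4)
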