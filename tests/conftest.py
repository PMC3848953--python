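import numpy as np
import pytest

from mtupf.models import StateSpaceModel
from mtupf.synthetic import MotivatingConfig, paper_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def motivating_cfg():
    return MotivatingConfig()


@pytest.fixture
def printed_data():
    return paper_dataset()


@pytest.fixture
def linear_model():
    """The one-state linear SDE with true parameters and log-normal q0."""
    cfg = MotivatingConfig()
    return StateSpaceModel(
        dim=1,
        drift=lambda x, t: -cfg.alpha * x + cfg.beta,
        diffusion=lambda x, t: np.array([[cfg.sigma]]),
        initial_sampler=lambda rng, n: np.exp(
            cfg.mu_q0 + cfg.sigma_q0 * rng.standard_normal((n, 1))),
        coord_names=["q"],
    )
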