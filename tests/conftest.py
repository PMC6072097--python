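import numpy as np
import pytest

from mtpbeta import FitConfig, SimDesign, TwoPartDataset, gen_two_part_beta

# the reference simulation condition: one Bernoulli(0.5) covariate,
# alpha = (1.5, 1), gamma = (-2.5, 1), phi = 1
REF_ALPHA = (1.5, 1.0)
REF_GAMMA = (-2.5, 1.0)
REF_PHI = 1.0


@pytest.fixture(scope="session")
def config():
    return FitConfig()


@pytest.fixture(scope="session")
def ref_design():
    return SimDesign(n=200, n_reps=1000, alpha=REF_ALPHA, gamma=REF_GAMMA,
                     phi=REF_PHI, seed=101)


@pytest.fixture(scope="session")
def ref_data():
    """One n=500 dataset from the reference condition."""
    return gen_two_part_beta(
        SimDesign(n=500, n_reps=1, alpha=REF_ALPHA, gamma=REF_GAMMA,
                  phi=REF_PHI, seed=7))


@pytest.fixture
def mixed_small_data():
    """Hand-built 5-observation dataset with zeros and positives."""
    y = np.array([0.0, 0.7, 0.0, 0.2, 0.35])
    x = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
    return TwoPartDataset(y, np.column_stack([np.ones(5), x]))


@pytest.fixture(scope="session")
def intercept_only_data():
    rng = np.random.default_rng(11)
    n = 300
    y = np.zeros(n)
    present = rng.random(n) < 0.8
    y[present] = rng.beta(0.3, 2.7, size=present.sum())
    y = np.clip(y, 0, 1 - 1e-12)
    y[(y > 0) & (y < 1e-12)] = 1e-6
    return TwoPartDataset(y, np.ones((n, 1)))
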