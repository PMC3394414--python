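import numpy as np
import pytest

from mdggm import GaussianGraphicalModel, random_ggm


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_random_model(n, seed, density=0.5):
    """A random dense-ish GGM for closed-form checks."""
    return random_ggm(n, density, seed)


@pytest.fixture
def model3(rng) -> GaussianGraphicalModel:
    """A fixed 3-variable model with correlations, used across oracle tests."""
    a = rng.normal(size=(3, 3))
    cov = a @ a.T + 3 * np.eye(3)
    return GaussianGraphicalModel.from_covariance(
        mean=np.array([0.5, -1.0, 2.0]), covariance=cov
    )


def well_separated_states(seed, n=6, scales=(1.0, 3.0, 9.0)):
    """GGMs sharing graph density but with covariances at different overall
    magnitudes — sub-states distinguishable by their fluctuation amplitude."""
    rng = np.random.default_rng(seed)
    out = []
    for scale in scales:
        m = random_ggm(n, 0.3, rng)
        out.append(GaussianGraphicalModel(mean=m.mean, precision=m.precision / scale))
    return out
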