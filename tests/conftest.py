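import numpy as np
import pytest

from gazehmm import GazeHMM, GaussianROI, make_archetypes
from gazehmm.preprocess import SAMPLE_INTERVAL_MS


@pytest.fixture(scope="session")
def archetypes():
    return make_archetypes()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_state_model():
    return GazeHMM(
        priors=[1.0],
        transitions=[[1.0]],
        emissions=[GaussianROI([960.0, 540.0], np.diag([150.0 ** 2, 150.0 ** 2]))],
    )


def make_stream(n=720, x=960.0, y=540.0, jitter=0.0, rng=None, missing=()):
    """Uniform 90 Hz stream at a point, optionally with missing indices."""
    t = np.arange(n) * SAMPLE_INTERVAL_MS
    xs = np.full(n, float(x))
    ys = np.full(n, float(y))
    if jitter and rng is not None:
        xs = xs + rng.normal(0, jitter, n)
        ys = ys + rng.normal(0, jitter, n)
    for i in missing:
        xs[i] = np.nan
        ys[i] = np.nan
    return t, xs, ys
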