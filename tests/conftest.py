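import warnings

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Max-iteration warnings are expected in coarse sweeps; keep logs clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fit_jgl stopped", category=RuntimeWarning)
        yield


def random_spd(rng, p, cond=5.0):
    """Random symmetric positive definite matrix with bounded conditioning."""
    Q, _ = np.linalg.qr(rng.normal(size=(p, p)))
    eig = rng.uniform(1.0, cond, size=p)
    return (Q * eig) @ Q.T
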