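import numpy as np
import pytest

from riemannbci import GeneratorConfig, SessionConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_spd(rng, n=4, scale=1.0):
    """Well-conditioned random SPD matrix: A A^T + scaled identity."""
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T + n * np.eye(n))


@pytest.fixture
def spd_factory(rng):
    def make(n=4, scale=1.0):
        return random_spd(rng, n=n, scale=scale)

    return make


@pytest.fixture
def small_session():
    """One-run, 8-trial artifact-free session (32 MI segments)."""
    cfg = GeneratorConfig(seed=123, trials_per_run=8, runs_per_session=1)
    return generate_session(cfg)


@pytest.fixture
def small_session_cfg():
    return SessionConfig(trials_per_run=8, runs_per_session=1)
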