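import numpy as np
import pytest

from dirswarm.model_core import ModelParams, SwarmState


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def default_params():
    return ModelParams()


def random_state(rng, n=None, spread=2.0):
    """Random swarm state with two stimulus groups."""
    n = n or int(rng.integers(2, 9))
    return SwarmState(
        positions=rng.normal(0.0, spread, size=(n, 2)),
        phases=rng.uniform(-np.pi, np.pi, n),
        gazes=rng.uniform(-np.pi, np.pi, n),
        spontaneous_freqs=rng.normal(4.0 * np.pi, 0.2, n),
        stimulus_phases=rng.uniform(-np.pi, np.pi, n),
        group_ids=np.where(np.arange(n) < n // 2, 1, 2),
    )
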