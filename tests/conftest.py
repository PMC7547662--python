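import numpy as np
import pytest

from decidecode._rng import substream
from decidecode.neural import NeuralGenParams, default_frequency_grid, generate_power_tensor
from decidecode.spectral import baseline_normalize
from decidecode.trials import generate_trial_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coin_trials():
    """One subject, choices by fair coin (null for all kernel analyses)."""
    return generate_trial_table(n_subjects=1, n_trials=2000, seed=7,
                                adaptive=False, choice_policy="coin")


@pytest.fixture(scope="session")
def observer_trials():
    """One staircase-titrated subject (accuracy ~75%), 500 analyzed trials."""
    t = generate_trial_table(n_subjects=1, n_trials=600, seed=11)
    return t.iloc[100:].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_tensor(observer_trials):
    """Baseline-normalized power tensor for the staircase subject."""
    params = NeuralGenParams(frequency_grid=default_frequency_grid(coarse=True))
    raw = generate_power_tensor(observer_trials, params,
                                rng=substream(11, "neural"))
    return baseline_normalize(raw)

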