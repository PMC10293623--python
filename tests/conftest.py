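import warnings

import numpy as np
import pytest

from mubeta import SimulationConfig, build_schedule, preprocess_raw, simulate_participant

warnings.filterwarnings("ignore", message="FastICA did not converge")


@pytest.fixture(scope="session")
def small_recording():
    """One participant, 2 runs (ME then MI) x 9 trials, blinks off."""
    config = SimulationConfig(n_runs=2, trials_per_condition=3, first_task="ME",
                              blink_rate_per_min=0.0)
    schedule = build_schedule(2, 3, (3, 5), seed=11, first_task="ME")
    return simulate_participant(config, schedule, participant_seed=101)


@pytest.fixture(scope="session")
def blinky_recording():
    """Same layout but with frequent blinks, for artifact tests."""
    config = SimulationConfig(n_runs=1, trials_per_condition=3, first_task="ME",
                              blink_rate_per_min=15.0)
    schedule = build_schedule(1, 3, (3, 5), seed=12, first_task="ME")
    return simulate_participant(config, schedule, participant_seed=102)


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    epochs, report, info = preprocess_raw(small_recording, skip_ica=True)
    return epochs


def make_epochs(data, fs=500.0, tmin=-2.0, tmax=7.0, conditions=None, tasks=None,
                labels=None, kinds=None):
    """Hand-built Epochs container for direct unit tests."""
    from mubeta.preprocess import Epochs

    n_trials, n_ch, _ = data.shape
    if labels is None:
        labels = [f"ch{i}" for i in range(n_ch)]
    if kinds is None:
        kinds = ["EEG"] * n_ch
    return Epochs(
        data=np.asarray(data, dtype=float), fs=fs, tmin=tmin, tmax=tmax,
        condition=np.array(conditions if conditions is not None else ["LEFT"] * n_trials, dtype=object),
        task=np.array(tasks if tasks is not None else ["ME"] * n_trials, dtype=object),
        kept=np.ones(n_trials, dtype=bool),
        channel_labels=list(labels), channel_kinds=list(kinds),
    )
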