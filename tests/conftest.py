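import numpy as np
import pytest

import trajrsa as T


@pytest.fixture(scope="session")
def mini_config():
    """12-stimulus miniature study used throughout the unit tests."""
    return T.SimulationConfig.miniature()


@pytest.fixture(scope="session")
def mini_stimuli(mini_config):
    return T.make_stimuli(mini_config)


@pytest.fixture(scope="session")
def mini_dataset(mini_config, mini_stimuli):
    """One simulated miniature study: raw trials, truth, preprocessed
    means, movement RDM series."""
    df, truth = T.simulate_trajectories(mini_stimuli, mini_config, seed=11)
    trials = T.load_trials(df)
    kept, _ = T.filter_trials(trials)
    kept, _ = T.filter_participants(kept)
    means = T.average_trajectories(T.mirror_to_canonical(kept, mini_stimuli), mini_stimuli)
    mov = T.movement_rdm_series(means)
    return {
        "df": df,
        "truth": truth,
        "trials": trials,
        "kept": kept,
        "means": means,
        "mov": mov,
    }


@pytest.fixture(scope="session")
def mini_neural(mini_config, mini_stimuli):
    series, truth = T.simulate_neural_rdms(mini_stimuli, mini_config, seed=11)
    return series, truth


def make_trial(
    t,
    x,
    y=None,
    participant="p0",
    index=0,
    stimulus="object_000",
    correct_side="left",
    midline=960.0,
):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return T.Trial(
        participant_id=participant,
        trial_index=index,
        stimulus_id=stimulus,
        block=0,
        correct_side=correct_side,
        midline_x=midline,
        t=t,
        x=x,
        y=y,
    )
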