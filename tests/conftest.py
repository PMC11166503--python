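import numpy as np
import pandas as pd
import pytest

import tntdecode as td
from tntdecode.epochs import EpochSet, Montage


@pytest.fixture(scope="session")
def montage():
    return Montage.standard_61()


@pytest.fixture(scope="session")
def default_sim():
    """One simulated participant with default (signal-bearing) amplitudes."""
    cfg = td.SimulationConfig(seed=3)
    epochs, truth = td.simulate_participant(cfg, 0)
    return cfg, epochs, truth


@pytest.fixture(scope="session")
def null_sim():
    """One participant with every signal amplitude at zero (pure noise)."""
    cfg = td.SimulationConfig(
        seed=4, cue_pattern_amp=0.0, scene_pattern_amp=0.0, cond_theta_amp=0.0,
        alpha_background_amp=0.0, forgetting_dz=0.0,
    )
    epochs, truth = td.simulate_participant(cfg, 0)
    return cfg, epochs, truth


def toy_epochs(
    data: np.ndarray,
    montage: Montage,
    sfreq: float = 250.0,
    t0: float = -1000.0,
    conditions=None,
    items=None,
) -> EpochSet:
    """Wrap an array as an EpochSet with a minimal trial table."""
    n_trials, n_ch, n_times = data.shape
    times = t0 + np.arange(n_times) * 1000.0 / sfreq
    table = pd.DataFrame(
        {
            "condition": conditions if conditions is not None else ["Think"] * n_trials,
            "item_id": items if items is not None else np.zeros(n_trials, dtype=int),
            "participant_id": 0,
        }
    )
    return EpochSet(
        data=data,
        times=times,
        sfreq=sfreq,
        channel_names=montage.channel_names[:n_ch],
        montage=montage,
        trial_table=table,
    )
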