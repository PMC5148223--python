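import numpy as np
import pandas as pd
import pytest

from cmrpipe.population import PopulationConfig, generate_trials, sample_population
from cmrpipe.stimuli import ScheduleConfig, build_schedule


@pytest.fixture(scope="session")
def small_dataset():
    """10-cell, 6-repeat NB/CM_long dataset used by oracle and invariant tests."""
    cfg = ScheduleConfig(masker_kinds=("NB", "CM_long"), laser_kinds=(),
                         include_fra=False, n_cycles=2, masking_blocks_per_cycle=3)
    sched = build_schedule(cfg, seed=11)
    pop = sample_population(PopulationConfig(n_cells=10, seed=12))
    return generate_trials(pop, sched, seed=13)


@pytest.fixture()
def toy_tables():
    """Hand-built spikes/trials pair with exactly known contents.

    Three NB noise-alone trials (ids 0-2) and two NB 5 dB trials (ids 3-4),
    one cell. Spike times chosen to hit specific analysis windows.
    """
    trials = pd.DataFrame({
        "trial_id": [0, 1, 2, 3, 4],
        "onset_s": [0.0, 4.0, 8.0, 12.0, 16.0],
        "masker_kind": pd.array(["NB"] * 5, dtype="string"),
        "snr_db": [np.nan, np.nan, np.nan, 5.0, 5.0],
        "laser": pd.array(["off"] * 5, dtype="string"),
        "fra_freq_hz": [np.nan] * 5,
        "fra_level_db": [np.nan] * 5,
    })
    spikes = pd.DataFrame({
        "cell_id": ["c1"] * 8,
        "trial_id": [0, 0, 1, 1, 2, 2, 3, 4],
        # six spikes inside [1.175, 1.275) across the three noise trials,
        # two signal-trial spikes in the same window
        "spike_time_s": [1.180, 1.200, 1.210, 1.220, 1.230, 1.270, 1.190, 1.260],
    })
    return spikes, trials
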