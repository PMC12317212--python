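import numpy as np
import pandas as pd
import pytest

import pupilforget as pf


@pytest.fixture(scope="session")
def tiny_experiment():
    """A small seeded experiment shared by read-only tests."""
    config = pf.SimulationConfig(n_subjects=4, n_items=8, seed=123)
    trials, traces, truth = pf.simulate_experiment(config)
    return config, trials, traces, truth


@pytest.fixture(scope="session")
def clean_experiment():
    """A blink-free experiment whose preprocessing keeps every trial."""
    config = pf.SimulationConfig(n_subjects=6, n_items=16, seed=9,
                                 blink_rate_per_s=0.0)
    trials, traces, truth = pf.simulate_experiment(config)
    clean, report = pf.preprocess_all(traces)
    return config, trials, clean, report


def make_trace(values, t0=-2000):
    """Wrap a 1-D value array into a single-trial TraceSet."""
    values = np.asarray(values, dtype=float)
    times = np.arange(t0, t0 + len(values))
    meta = pd.DataFrame({"subject": [0], "trial": [0]})
    return pf.TraceSet(times, values[None, :], meta)
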