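import numpy as np
import pytest

from trpquant import TraceSimConfig, default_windows, simulate_calcium_traces
from trpquant.calibration import calibrate_traces


@pytest.fixture(scope="session")
def windows():
    """Baseline 0-60 s, agonist 60-120 s, ionomycin 140-170 s."""
    return default_windows(agonist_name="THC")


@pytest.fixture(scope="session")
def small_cohort(windows):
    """60 simulated cells with ground truth and their calibrated traces."""
    config = TraceSimConfig(n_cells=60, seed=11)
    trace_set, truth = simulate_calcium_traces(config, windows)
    calcium = calibrate_traces(trace_set.traces, trace_set.background, config.calibration)
    return config, trace_set, truth, calcium


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
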