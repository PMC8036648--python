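import numpy as np
import pytest
from hypothesis import settings

import perimon as pm

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_window():
    """One clean 5-min rendered PPG window at 20 Hz with its ground truth."""
    cfg = pm.PpgSimConfig(mean_hr=70, calibration_s=0.0, seed=42)
    ts_ms, x, truth = pm.simulate_session(cfg, 300.0)
    return pm.PpgStream(ts_ms, x, cfg.sampling_rate), truth, cfg


@pytest.fixture(scope="session")
def clean_nn(clean_window):
    stream, truth, _ = clean_window
    nn, labels = pm.stream_to_nn(stream)
    return nn, labels, truth


def make_nn(nn_ms, start_ms=0.0):
    """Build an NnSeries directly from a list of intervals (ms)."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    beats = np.concatenate([[start_ms], start_ms + np.cumsum(nn_ms)])
    return pm.NnSeries(
        beat_times_ms=beats,
        nn_times_ms=beats[1:],
        nn_ms=nn_ms,
        removed_fraction=0.0,
    )
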