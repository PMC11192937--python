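import numpy as np
import pytest

import tremorkit as tk


@pytest.fixture
def cfg():
    return tk.PipelineConfig()


@pytest.fixture
def board_cal():
    """0.9 mm/px, the scale a 63 mm / 70 px interpupillary distance gives."""
    return tk.CalibrationInfo(scale=0.9, source="board")


@pytest.fixture
def clean_params():
    """Noiseless 5 Hz, 10 mm peak-to-peak simulation (60 Hz, 30 s)."""
    return tk.TremorSimParams(f0=5.0, app_mm=10.0, jitter_sd_px=0.0,
                              drift_amp_mm=0.0, dropout_rate=0.0,
                              spike_rate_per_min=0.0, seed=11)


@pytest.fixture
def clean_series(clean_params):
    ts, truth = tk.simulate_keypoint_tremor(clean_params)
    return ts, truth


def make_signal(samples, fs=60.0, units="mm", **kw):
    return tk.TremorSignal(samples=np.asarray(samples, dtype=float),
                           sample_rate=fs, units=units, **kw)
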