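"""Conditioning, filtering, calibration and signal extraction."""

import numpy as np
import pytest
from scipy import signal as sps

import tremorkit as tk
from tremorkit.io_formats import ParameterError, QualityError
from tremorkit.preprocessing import _bandpass_array, bandpass_gain

from conftest import make_signal


def flat_series(n=150, fs=60.0, value=0.0):
    n_lm = len(tk.HAND_LANDMARKS)
    coords = np.full((n, n_lm, 2), value)
    conf = np.ones((n, n_lm))
    return tk.KeypointTimeSeries(frame_rate=fs, hand="right",
                                 coords=coords, confidence=conf)


class TestConditioning:
    def test_low_confidence_frame_interpolated(self):
        ts = flat_series()
        ts.coords[9:12, :, :] = np.array(
            [[0.0, 0.0], [5.0, 7.0], [2.0, 2.0]])[:, None, :]
        ts.confidence[10, :] = 0.4
        out = tk.condition_keypoints(ts)
        np.testing.assert_allclose(out.coords[10, 0], [1.0, 1.0])
        assert out.provenance["n_low_confidence"] == len(tk.HAND_LANDMARKS)

    def test_spike_masked_and_interpolated(self):
        ts = flat_series()
        ts.coords[50, :, 0] += 150.0
        out = tk.condition_keypoints(ts)
        np.testing.assert_allclose(out.coords[50], ts.coords[49])
        assert out.provenance["n_spikes"] == len(tk.HAND_LANDMARKS)

    def test_boundary_100px_jump_kept(self):
        # "over 100 px" is strict: exactly 100 px survives
        ts = flat_series()
        ts.coords[50:, :, 0] += 100.0
        out = tk.condition_keypoints(ts)
        assert out.provenance["n_spikes"] == 0
        np.testing.assert_array_equal(out.coords, ts.coords)

    def test_clean_input_identity(self):
        ts = flat_series()
        out = tk.condition_keypoints(ts)
        np.testing.assert_array_equal(out.coords, ts.coords)
        np.testing.assert_array_equal(out.confidence, ts.confidence)

    def test_idempotent(self):
        ts, _ = tk.simulate_keypoint_tremor(
            tk.TremorSimParams(dropout_rate=0.05, spike_rate_per_min=5.0,
                               seed=21))
        once = tk.condition_keypoints(ts)
        twice = tk.condition_keypoints(once)
        np.testing.assert_array_equal(once.coords, twice.coords)
        assert twice.provenance["n_interpolated"] == 0

    def test_majority_masked_rejected(self):
        ts = flat_series(n=150)
        ts.confidence[: 90, :] = 0.1
        with pytest.raises(QualityError, match="50%"):
            tk.condition_keypoints(ts)

    def test_long_edge_gap_rejected(self):
        ts = flat_series(n=300)
        ts.confidence[:70, :] = 0.1  # >1 s leading gap at 60 Hz
        with pytest.raises(QualityError, match="edge"):
            tk.condition_keypoints(ts)

    def test_too_short_rejected(self):
        with pytest.raises(QualityError, match="2 s"):
            tk.condition_keypoints(flat_series(n=100))


class TestBandpass:
    def test_dc_rejected(self):
        sig = make_signal(np.full(1800, 50.0))
        out = tk.bandpass(sig)
        assert np.abs(out.samples).max() < 1e-6 * 50.0

    def test_5hz_preserved_within_1pct(self, cfg):
        # oracle: the designed filter's squared magnitude response at 5 Hz
        t = np.arange(1800) / 60.0
        sig = make_signal(np.sin(2 * np.pi * 5 * t))
        out = tk.bandpass(sig)
        gain_oracle = bandpass_gain(np.array([5.0]), 60.0, cfg)[0]
        steady = out.samples[300:-300]
        assert np.abs(steady).max() == pytest.approx(gain_oracle, rel=0.01)
        assert abs(gain_oracle - 1.0) < 0.01

    def test_drift_attenuated_40db(self, cfg):
        gain = bandpass_gain(np.array([0.2]), 60.0, cfg)[0]
        assert 20 * np.log10(gain) < -40
        t = np.arange(3600) / 60.0
        sig = make_signal(50 * np.sin(2 * np.pi * 0.2 * t)
                          + 5 * np.sin(2 * np.pi * 5 * t))
        out = tk.bandpass(sig)
        # residual drift measured at the 0.2 Hz bin of the filtered signal
        spectrum = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out.samples), 1 / 60.0)
        drift_bin = np.argmin(np.abs(freqs - 0.2))
        tremor_bin = np.argmin(np.abs(freqs - 5.0))
        in_drift = np.abs(np.fft.rfft(sig.samples))[drift_bin]
        assert 20 * np.log10(spectrum[drift_bin] / in_drift) < -40
        assert spectrum[tremor_bin] > 100 * spectrum[drift_bin]

    def test_nyquist_violation_rejected(self):
        sig = make_signal(np.zeros(100), fs=15.0)
        with pytest.raises(ParameterError, match="Nyquist"):
            tk.bandpass(sig)

    def test_scaling_commutes_with_filtering(self, cfg):
        rng = np.random.default_rng(22)
        x = rng.normal(size=1200)
        a = _bandpass_array(3.7 * x, 60.0, cfg)
        b = 3.7 * _bandpass_array(x, 60.0, cfg)
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)


class TestCalibration:
    @pytest.mark.parametrize("mm,px,expected", [(63.0, 70.0, 0.9),
                                                (60.0, 60.0, 1.0)])
    def test_ipd_scale(self, mm, px, expected):
        cal = tk.compute_scale(mm, px)
        assert cal.scale == pytest.approx(expected)
        assert cal.source == "ipd"

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            tk.compute_scale(63.0, 0.0)


class TestExtractSignal:
    def test_horizontal_oscillation_projects_to_x(self, board_cal):
        ts, _ = tk.simulate_keypoint_tremor(
            tk.TremorSimParams(angle_rad=0.0, jitter_sd_px=0.0,
                               drift_amp_mm=0.0, dropout_rate=0.0,
                               spike_rate_per_min=0.0, seed=23))
        sig = tk.extract_signal(ts, "postural", board_cal)
        j = ts.landmark_index("middle_finger_tip")
        x_mm = _bandpass_array(ts.coords[:, j, 0] - ts.coords[:, j, 0].mean(),
                               60.0, tk.PipelineConfig()) * 0.9
        match = min(np.abs(sig.samples - x_mm).max(),
                    np.abs(sig.samples + x_mm).max())
        assert match < 1e-9
        assert sig.provenance["directionality"] > 0.99

    def test_circular_motion_flags_direction_ambiguity(self, board_cal):
        ts, _ = tk.simulate_keypoint_tremor(
            tk.TremorSimParams(circular=True, jitter_sd_px=0.0,
                               drift_amp_mm=0.0, dropout_rate=0.0,
                               spike_rate_per_min=0.0, seed=24))
        sig = tk.extract_signal(ts, "postural", board_cal)
        assert sig.provenance["directionality"] == pytest.approx(0.5, abs=0.05)
        assert any("direction-ambiguous" in w
                   for w in sig.provenance.get("warnings", []))

    def test_uncalibrated_output_in_px_and_flagged(self):
        ts, _ = tk.simulate_keypoint_tremor(tk.TremorSimParams(seed=25))
        sig = tk.extract_signal(tk.condition_keypoints(ts), "postural")
        assert sig.units == "px"
        assert sig.provenance["non_metric"]

    def test_missing_landmark_rejected(self):
        ts, _ = tk.simulate_keypoint_tremor(tk.TremorSimParams(seed=26))
        names = list(ts.landmark_names)
        keep = [i for i, n in enumerate(names) if n != "middle_finger_tip"]
        trimmed = tk.KeypointTimeSeries(
            frame_rate=ts.frame_rate, hand=ts.hand,
            coords=ts.coords[:, keep], confidence=ts.confidence[:, keep],
            landmark_names=tuple(names[i] for i in keep))
        with pytest.raises(ParameterError, match="middle_finger_tip"):
            tk.extract_signal(trimmed, "postural")

    def test_full_chain_preserves_amplitude_within_2pct(self, board_cal,
                                                        clean_series):
        ts, truth = clean_series
        sig = tk.analyze_chain(ts, "postural", board_cal)
        steady = sig.samples[120:-120]  # trim filter edges
        assert np.ptp(steady) == pytest.approx(truth["app_mm"], rel=0.02)

    def test_kinetic_extraction_segments_bursts(self, board_cal):
        ts, _ = tk.simulate_keypoint_tremor(
            tk.TremorSimParams(jitter_sd_px=0.2, drift_amp_mm=0.0,
                               dropout_rate=0.0, spike_rate_per_min=0.0,
                               seed=27))
        # gate the middle third off to mimic pauses between pointing bursts
        ts.coords[600:1200] = ts.coords[600:1200].mean(axis=0, keepdims=True)
        sig = tk.extract_signal(tk.condition_keypoints(ts), "kinetic", board_cal)
        assert sig.source_landmark == "index_finger_tip"
        assert len(sig.segments) >= 2
        covered = sum(b - a for a, b in sig.segments)
        assert covered < 0.8 * len(sig.samples)
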