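"""Wrist-accelerometer reference pipeline.

Accelerometry is the clinical gold standard for tremor *frequency*; this
module mirrors the classic analysis chain: pick the axis with the largest
band-passed range of variation, band-pass 1-10 Hz with a 5th-order
Butterworth filter (applied forward-backward, so zero phase), segment
kinetic trials by thresholding the moving average of the rectified signal,
and estimate the dominant frequency per trial from a Welch power spectral
density with rectangular 1 s windows and 0.5 s overlap (1 Hz bins).
Amplitude is never estimated from acceleration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_formats import AccelRecording, ParameterError, PipelineConfig, QualityError


@dataclass
class AccelFrequencySummary:
    """Dominant tremor frequency summarised across trials of one recording."""

    dominant_frequency_hz: float
    frequency_sd_hz: float
    per_trial_peaks: list[float]
    selected_axis: int
    n_trials: int


def bandpass_accel(x: np.ndarray, sample_rate: float,
                   cfg: PipelineConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 5th order, 1-10 Hz)."""
    cfg = cfg or PipelineConfig()
    if cfg.bandpass_high >= sample_rate / 2:
        raise ParameterError(
            f"bandpass_high={cfg.bandpass_high} Hz violates Nyquist at "
            f"{sample_rate} Hz sampling")
    sos = sps.butter(cfg.accel_filter_order,
                     [cfg.bandpass_low, cfg.bandpass_high],
                     btype="band", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def select_axis(rec: AccelRecording, cfg: PipelineConfig | None = None) -> int:
    """Index of the axis with the highest band-passed range of variation.

    The band-pass removes constant offsets (gravity) before ranging; ties are
    broken toward the lowest index.
    """
    cfg = cfg or PipelineConfig()
    if rec.duration_s < 2:
        raise ParameterError("need at least 2 s of data to select an axis")
    ranges = [np.ptp(bandpass_accel(ax, rec.sample_rate, cfg)) for ax in rec.data]
    return int(np.argmax(ranges))


def segment_kinetic(x: np.ndarray, sample_rate: float,
                    cfg: PipelineConfig | None = None) -> list[tuple[int, int]]:
    """Movement-burst intervals of a band-passed kinetic-trial signal.

    The envelope is a moving average (default 0.5 s) of ``|x|``; samples where
    it exceeds ``envelope_threshold_frac`` of its ``envelope_percentile``-th
    percentile are active.  Active runs closer than ``segment_merge_gap_s``
    are merged and runs shorter than ``segment_min_s`` dropped.  Returns
    half-open ``[start, stop)`` sample intervals.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(x, dtype=float)
    win = max(1, int(round(cfg.envelope_window_s * sample_rate)))
    kernel = np.ones(win) / win
    envelope = np.convolve(np.abs(x), kernel, mode="same")
    level = cfg.envelope_threshold_frac * np.percentile(
        envelope, cfg.envelope_percentile)
    active = envelope > level
    if not active.any():
        warnings.warn("no active samples found during kinetic segmentation",
                      stacklevel=2)
        return []
    # run-length encode the active mask
    bounds = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    segments = [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, len(bounds), 2)]
    # merge gaps shorter than the merge threshold
    merged: list[tuple[int, int]] = []
    gap = cfg.segment_merge_gap_s * sample_rate
    for seg in segments:
        if merged and seg[0] - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(seg)
    min_len = cfg.segment_min_s * sample_rate
    return [s for s in merged if s[1] - s[0] >= min_len]


def _welch_peak(x: np.ndarray, sample_rate: float, cfg: PipelineConfig) -> float:
    """Dominant in-band frequency of one trial via the classic Welch PSD."""
    nperseg = int(round(cfg.stft_window_s * sample_rate))
    f, psd = sps.welch(x, fs=sample_rate, window="boxcar", nperseg=nperseg,
                       noverlap=nperseg // 2)
    band = (f >= cfg.bandpass_low) & (f <= cfg.bandpass_high)
    fb, pb = f[band], psd[band]
    return float(fb[int(np.argmax(pb))])


def accel_dominant_frequency(rec: AccelRecording,
                             cfg: PipelineConfig | None = None
                             ) -> AccelFrequencySummary:
    """Dominant tremor frequency of an accelerometer recording.

    Postural recordings are analysed as a single trial after dropping the
    first and last second (an automatable proxy for trimming voluntary arm
    movements at the trial edges).  Kinetic recordings are split into
    movement bursts by :func:`segment_kinetic`, one trial per burst.  The
    summary is the mean and SD (ddof=1; 0 for a single trial) of the
    per-trial Welch peaks.
    """
    cfg = cfg or PipelineConfig()
    axis = select_axis(rec, cfg)
    x = bandpass_accel(rec.data[axis], rec.sample_rate, cfg)
    fs = rec.sample_rate
    if rec.condition == "kinetic":
        intervals = segment_kinetic(x, fs, cfg)
        trials = [x[a:b] for a, b in intervals]
    else:
        edge = int(round(fs))
        trimmed = x[edge:-edge] if len(x) > 2 * edge else x
        trials = [trimmed]
    trials = [t for t in trials if len(t) >= int(round(cfg.stft_window_s * fs))]
    if not trials:
        raise QualityError("no analysable trials in recording")
    peaks = [_welch_peak(t, fs, cfg) for t in trials]
    sd = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else 0.0
    return AccelFrequencySummary(
        dominant_frequency_hz=float(np.mean(peaks)), frequency_sd_hz=sd,
        per_trial_peaks=[float(p) for p in peaks], selected_axis=axis,
        n_trials=len(peaks))
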