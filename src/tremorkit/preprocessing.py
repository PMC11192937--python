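"""From raw keypoint series to a clean, calibrated 1-D tremor signal.

The chain is: mask low-confidence points (< 0.5 by default) and spikes
(jumps over 100 px from the previous *retained* frame, so a spike cannot
poison its successor), linearly interpolate masked cells, convert the
tracked fingertip's 2-D trajectory to a scalar displacement by projecting
the band-passed x/y series onto its principal oscillation axis, and scale
px to mm via the calibration factor.

The reduction from 2-D motion to one scalar is a package choice (trackers
only give coordinates): the first principal component captures the full
excursion of a linear tremor regardless of its direction in the image, and
the recorded directionality index (variance fraction on that component)
makes non-linear motion visible — below 0.6 a warning lands in the signal's
provenance because the amplitude is then direction-ambiguous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .accel import segment_kinetic
from .io_formats import (
    KINETIC_LANDMARK,
    POSTURAL_LANDMARK,
    CalibrationInfo,
    KeypointTimeSeries,
    ParameterError,
    PipelineConfig,
    QualityError,
)


@dataclass
class TremorSignal:
    """Calibrated 1-D displacement series for one hand and condition.

    ``segments`` lists half-open ``[start, stop)`` sample intervals of
    analysable activity (the whole record for postural signals, movement
    bursts for kinetic ones).
    """

    samples: np.ndarray
    sample_rate: float
    units: str = "mm"                      # "mm" or "px" (uncalibrated)
    source_landmark: str = POSTURAL_LANDMARK
    condition: str = "postural"
    provenance: dict = field(default_factory=dict)
    segments: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.units not in ("mm", "px"):
            raise ParameterError("units must be 'mm' or 'px'")
        if not np.isfinite(self.samples).all():
            raise ParameterError("tremor signal must be finite after conditioning")
        if self.segments is None:
            self.segments = [(0, len(self.samples))]

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def replace(self, **changes) -> "TremorSignal":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def condition_keypoints(ts: KeypointTimeSeries,
                        cfg: PipelineConfig | None = None) -> KeypointTimeSeries:
    """Mask unreliable keypoints and repair them by linear interpolation.

    A (frame, landmark) cell is masked when its confidence falls below the
    threshold, when it was already flagged missing, or when the landmark's
    position jumps more than ``spike_jump_px`` from its previous retained
    position.  Masked cells are linearly interpolated from the nearest
    retained neighbours (edge gaps take the nearest retained value; edge
    gaps longer than 1 s abort).  The operation is idempotent: repaired
    cells get confidence 1.0 and lie on straight lines, so a second pass
    changes nothing.

    Provenance records the exact masks (``mask_low_confidence``,
    ``mask_spike``) and summary counts.
    """
    cfg = cfg or PipelineConfig()
    if ts.n_frames < 2 * ts.frame_rate:
        raise QualityError("need at least 2 s of keypoint data")
    coords = ts.coords.copy()
    conf = ts.confidence.copy()
    n_frames, n_lm, _ = coords.shape

    low_conf = (conf < cfg.confidence_threshold) | ts.missing
    spike = np.zeros((n_frames, n_lm), dtype=bool)
    for j in range(n_lm):
        retained = np.flatnonzero(~low_conf[:, j])
        if retained.size == 0:
            raise QualityError(f"landmark {ts.landmark_names[j]!r}: all frames masked")
        last = retained[0]
        for f in retained[1:]:
            jump = np.linalg.norm(coords[f, j] - coords[last, j])
            if jump > cfg.spike_jump_px:     # strict: exactly 100 px is kept
                spike[f, j] = True
            else:
                last = f
    masked = low_conf | spike

    max_edge = int(np.ceil(ts.frame_rate))   # 1 s
    for j in range(n_lm):
        keep = np.flatnonzero(~masked[:, j])
        if keep.size < n_frames / 2:
            raise QualityError(
                f"landmark {ts.landmark_names[j]!r}: >50% of frames masked")
        if keep[0] > max_edge or (n_frames - 1 - keep[-1]) > max_edge:
            raise QualityError(
                f"landmark {ts.landmark_names[j]!r}: masked run >1 s at an edge")
        gaps = np.flatnonzero(masked[:, j])
        if gaps.size:
            for a in range(coords.shape[2]):
                coords[gaps, j, a] = np.interp(gaps, keep, coords[keep, j, a])
            conf[gaps, j] = 1.0

    provenance = {
        "n_low_confidence": int(low_conf.sum()),
        "n_spikes": int(spike.sum()),
        "n_interpolated": int(masked.sum()),
        "mask_low_confidence": low_conf,
        "mask_spike": spike,
    }
    return KeypointTimeSeries(
        frame_rate=ts.frame_rate, hand=ts.hand, coords=coords, confidence=conf,
        landmark_names=ts.landmark_names,
        missing=np.zeros((n_frames, n_lm), dtype=bool), provenance=provenance)


# ---------------------------------------------------------------------------
# filtering and calibration
# ---------------------------------------------------------------------------

def _bandpass_array(x: np.ndarray, sample_rate: float,
                    cfg: PipelineConfig) -> np.ndarray:
    if cfg.bandpass_high >= sample_rate / 2:
        raise ParameterError(
            f"bandpass_high={cfg.bandpass_high} Hz violates Nyquist at "
            f"{sample_rate} Hz sampling")
    sos = sps.butter(cfg.filter_order, [cfg.bandpass_low, cfg.bandpass_high],
                     btype="band", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def bandpass_gain(freqs: np.ndarray, sample_rate: float,
                  cfg: PipelineConfig) -> np.ndarray:
    """Amplitude gain of one zero-phase band-pass application at ``freqs``.

    Forward-backward filtering applies the filter twice, so the gain is the
    squared magnitude response.  Downstream amplitude estimates divide by
    this to undo the mild passband droop near the band edges.
    """
    sos = sps.butter(cfg.filter_order, [cfg.bandpass_low, cfg.bandpass_high],
                     btype="band", fs=sample_rate, output="sos")
    w, h = sps.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=sample_rate)
    return np.abs(h) ** 2


def bandpass(signal: TremorSignal, cfg: PipelineConfig | None = None) -> TremorSignal:
    """Zero-phase Butterworth band-pass (default 4th order, 1-10 Hz).

    Forward-backward filtering keeps amplitude peaks phase-aligned with the
    raw motion; DC and sub-1 Hz drift are rejected, tremor-band content
    preserved.
    """
    cfg = cfg or PipelineConfig()
    provenance = dict(signal.provenance)
    provenance["n_bandpass_applications"] = provenance.get(
        "n_bandpass_applications", 0) + 1
    return signal.replace(samples=_bandpass_array(signal.samples,
                                                  signal.sample_rate, cfg),
                          provenance=provenance)


def compute_scale(ipd_mm: float, ipd_px: float) -> CalibrationInfo:
    """mm/px scale from the interpupillary distance (real mm / video px)."""
    if ipd_mm <= 0 or ipd_px <= 0:
        raise ParameterError("ipd_mm and ipd_px must both be > 0")
    return CalibrationInfo(scale=ipd_mm / ipd_px, source="ipd",
                           ipd_mm=ipd_mm, ipd_px=ipd_px)


# ---------------------------------------------------------------------------
# signal extraction
# ---------------------------------------------------------------------------

def extract_signal(ts: KeypointTimeSeries, condition: str = "postural",
                   cal: CalibrationInfo | None = None,
                   cfg: PipelineConfig | None = None) -> TremorSignal:
    """Scalar tremor displacement of the condition's fingertip landmark.

    Postural tremor is read from the middle fingertip, kinetic tremor from
    the index fingertip.  The landmark's x/y series (z, when present, is
    ignored by default) are band-passed and projected onto their first
    principal axis; the projection is scaled to mm when a calibration is
    available, else left in px and flagged non-metric.  For kinetic data the
    movement bursts are detected with the same envelope rule as the
    accelerometer pipeline and recorded as ``segments``.
    """
    cfg = cfg or PipelineConfig()
    cal = cal or CalibrationInfo(scale=1.0, source="none")
    if condition not in ("postural", "kinetic"):
        raise ParameterError("condition must be 'postural' or 'kinetic'")
    landmark = POSTURAL_LANDMARK if condition == "postural" else KINETIC_LANDMARK
    j = ts.landmark_index(landmark)
    xy = ts.coords[:, j, :2]
    if not np.isfinite(xy).all():
        raise QualityError("series must be conditioned before extraction "
                           "(non-finite coordinates present)")
    filtered = _bandpass_array(xy - xy.mean(axis=0), ts.frame_rate, cfg)

    cov = np.cov(filtered.T)
    evals, evecs = np.linalg.eigh(cov)       # ascending
    principal = evecs[:, -1]
    if principal[np.argmax(np.abs(principal))] < 0:
        principal = -principal
    projected = filtered @ principal
    total = float(evals.sum())
    directionality = float(evals[-1] / total) if total > 0 else 1.0

    provenance = dict(ts.provenance)
    provenance["n_bandpass_applications"] = 1
    provenance["directionality"] = directionality
    provenance["principal_axis"] = principal
    if directionality < 0.6:
        provenance["warnings"] = provenance.get("warnings", []) + [
            f"directionality {directionality:.2f} < 0.6: motion is not "
            "linear, amplitude is direction-ambiguous"]

    if cal.source == "none":
        units, scaled = "px", projected
        provenance["non_metric"] = True
    else:
        units, scaled = "mm", projected * cal.scale

    segments = None
    if condition == "kinetic":
        segments = segment_kinetic(scaled, ts.frame_rate, cfg)
        if not segments:
            raise QualityError("no movement bursts found in kinetic recording")
    return TremorSignal(samples=scaled, sample_rate=ts.frame_rate, units=units,
                        source_landmark=landmark, condition=condition,
                        provenance=provenance, segments=segments)


def analyze_chain(ts: KeypointTimeSeries, condition: str = "postural",
                  cal: CalibrationInfo | None = None,
                  cfg: PipelineConfig | None = None) -> TremorSignal:
    """Convenience: conditioning followed by signal extraction."""
    cfg = cfg or PipelineConfig()
    return extract_signal(condition_keypoints(ts, cfg), condition, cal, cfg)
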