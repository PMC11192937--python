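"""Synthetic keypoint, accelerometer and cohort data with known ground truth.

Every downstream stage of the package is testable against these generators
without any recorded patient data.  The keypoint simulator emulates the
structure of tracker output from tremor videos: a 4-8 Hz oscillation of
2-40 mm peak-to-peak along a fixed in-plane axis, an optional even harmonic
at exactly twice the dominant frequency, a slow (<1 Hz) sinusoidal arm
drift, white Gaussian prediction jitter, confidence dropouts and occasional
>100 px spike artefacts.  Every generator is a pure function of its seed
and returns a serialisable ground-truth record next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_formats import (
    HAND_LANDMARKS,
    AccelRecording,
    KeypointTimeSeries,
    ParameterError,
    QualityError,
)

# static hand layout (px offsets from the wrist) used as the resting pose;
# the whole hand moves rigidly with the tremor, so the layout itself is
# irrelevant to amplitude/frequency
_BASE = {"wrist": (0.0, 0.0)}
_DIGIT_DIR = {"thumb": (-40.0, -20.0), "index_finger": (-15.0, -60.0),
              "middle_finger": (0.0, -65.0), "ring_finger": (15.0, -60.0),
              "pinky": (30.0, -50.0)}
for _name in HAND_LANDMARKS[1:]:
    _digit, _joint = _name.rsplit("_", 1)
    _frac = {"cmc": 0.3, "mcp": 0.45, "pip": 0.65, "ip": 0.65,
             "dip": 0.85, "tip": 1.0}[_joint]
    _dx, _dy = _DIGIT_DIR[_digit]
    _BASE[_name] = (_dx * _frac, _dy * _frac)

BASE_LAYOUT = np.array([_BASE[n] for n in HAND_LANDMARKS])  # (21, 2) px
HAND_ORIGIN = np.array([640.0, 360.0])                      # px, image centre


@dataclass
class TremorSimParams:
    """Generating parameters of one simulated keypoint recording.

    Defaults describe a typical essential-tremor video trial: 5 Hz tremor of
    10 mm peak-to-peak recorded at 60 Hz for 30 s, 0.9 mm/px scale
    (interpupillary-distance calibration), mild drift, half-pixel tracking
    jitter, 2 % confidence dropouts and about one spike artefact per minute.
    """

    f0: float = 5.0
    app_mm: float = 10.0
    harmonic_rel_amp: float = 0.0
    drift_amp_mm: float = 5.0
    drift_freq_hz: float = 0.3
    jitter_sd_px: float = 0.5
    dropout_rate: float = 0.02
    spike_rate_per_min: float = 1.0
    duration_s: float = 30.0
    frame_rate: float = 60.0
    scale_mm_per_px: float = 0.9
    phase0: float = 0.0
    angle_rad: float | None = None   # None -> uniform random direction
    circular: bool = False           # stress option: equal quadrature motion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 >= self.frame_rate / 2:
            raise ParameterError("f0 must be below the Nyquist frequency")
        if self.app_mm < 0:
            raise ParameterError("app_mm must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.drift_freq_hz >= 1.0:
            raise ParameterError("drift is by definition below 1 Hz")


@dataclass
class CohortSimParams:
    """Generating model of a synthetic DBS cohort.

    Baseline kinematics are Gaussian per feature (frequency means follow the
    reported group values, ~5.75 Hz kinetic / 5.9 Hz postural); the binary
    response follows a logistic model on the raw features whose default
    coefficients place ~55 % poor responders with a per-mm log-odds of
    ln(1/0.89) on baseline kinetic amplitude.  The post-stimulation
    amplitude is drawn from a label-conditional relative-reduction model.
    """

    n_patients: int = 58
    beta: np.ndarray | None = None   # intercept + one coefficient per feature
    feature_means: tuple[float, ...] = (35.0, 25.0, 5.75, 5.9)
    feature_sds: tuple[float, ...] = (10.0, 10.0, 0.58, 0.58)
    reduction_good: tuple[float, float] = (0.70, 0.12)   # mean, sd
    reduction_poor: tuple[float, float] = (0.12, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")
        if any(s <= 0 for s in self.feature_sds):
            raise ParameterError("feature SDs must be > 0")
        if self.beta is None:
            self.beta = DEFAULT_COHORT_BETA.copy()
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.feature_means) + 1,):
            raise ParameterError("beta must have length n_features + 1")


COHORT_FEATURES = ("peak_kinetic_amplitude_mm", "peak_postural_amplitude_mm",
                   "dominant_kinetic_frequency_hz", "dominant_postural_frequency_hz")
#: log-odds of a *poor* response; intercept set for 55 % poor prevalence at
#: the feature means, slope on kinetic amplitude = -ln(0.89) per mm
DEFAULT_COHORT_BETA = np.array(
    [np.log(0.55 / 0.45) - (-np.log(0.89)) * 35.0, -np.log(0.89), 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# keypoint simulators
# ---------------------------------------------------------------------------

def _assemble_keypoints(disp_px: np.ndarray, params: TremorSimParams,
                        rng: np.random.Generator, hand: str = "right"
                        ) -> tuple[KeypointTimeSeries, dict]:
    """Embed a (n_frames, 2) px displacement into a full 21-landmark series,
    adding jitter, dropouts and spikes; returns the series + artefact record."""
    n = disp_px.shape[0]
    coords = (HAND_ORIGIN[None, None, :] + BASE_LAYOUT[None, :, :]
              + disp_px[:, None, :])
    coords = coords + rng.normal(0.0, params.jitter_sd_px, size=coords.shape)

    confidence = rng.uniform(0.8, 1.0, size=(n, len(HAND_LANDMARKS)))
    edge = int(np.ceil(params.frame_rate))   # keep edges clean (<=1 s gaps rule)
    interior = np.arange(edge, max(edge + 1, n - edge))
    dropout_frames = interior[rng.random(len(interior)) < params.dropout_rate]
    confidence[dropout_frames, :] = rng.uniform(
        0.05, 0.45, size=(len(dropout_frames), len(HAND_LANDMARKS)))

    p_spike = params.spike_rate_per_min / 60.0 / params.frame_rate
    spike_frames = interior[rng.random(len(interior)) < p_spike]
    spike_frames = np.setdiff1d(spike_frames, dropout_frames)
    for f in spike_frames:
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        coords[f] += direction * rng.uniform(150.0, 300.0)

    ts = KeypointTimeSeries(frame_rate=params.frame_rate, hand=hand,
                            coords=coords, confidence=confidence)
    artefacts = {"dropout_frames": dropout_frames.tolist(),
                 "spike_frames": spike_frames.tolist()}
    return ts, artefacts


def simulate_keypoint_tremor(params: TremorSimParams
                             ) -> tuple[KeypointTimeSeries, dict]:
    """Simulate one hand's keypoint series with a known tremor.

    The whole hand oscillates rigidly along a fixed in-plane axis with
    peak-to-peak displacement ``app_mm`` at ``f0`` (plus the optional
    harmonic at exactly 2*f0 and the slow drift along an independent axis).
    The ground-truth record stores amplitude, frequency, harmonic presence,
    motion axis and the injected artefact frames.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.frame_rate))
    t = np.arange(n) / params.frame_rate
    angle = (rng.uniform(0, 2 * np.pi) if params.angle_rad is None
             else params.angle_rad)
    axis = np.array([np.cos(angle), np.sin(angle)])

    a_px = (params.app_mm / 2.0) / params.scale_mm_per_px
    fundamental = a_px * np.sin(2 * np.pi * params.f0 * t + params.phase0)
    harmonic = (params.harmonic_rel_amp * a_px
                * np.sin(2 * np.pi * 2 * params.f0 * t + rng.uniform(0, 2 * np.pi)))
    if params.circular:
        quad = a_px * np.cos(2 * np.pi * params.f0 * t + params.phase0)
        ortho = np.array([-axis[1], axis[0]])
        disp = (np.outer(fundamental + harmonic, axis) + np.outer(quad, ortho))
    else:
        disp = np.outer(fundamental + harmonic, axis)

    drift_axis_angle = rng.uniform(0, 2 * np.pi)
    drift_axis = np.array([np.cos(drift_axis_angle), np.sin(drift_axis_angle)])
    drift_px = (params.drift_amp_mm / params.scale_mm_per_px
                * np.sin(2 * np.pi * params.drift_freq_hz * t + rng.uniform(0, 2 * np.pi)))
    disp = disp + np.outer(drift_px, drift_axis)

    ts, artefacts = _assemble_keypoints(disp, params, rng)
    truth = {"f0": params.f0, "app_mm": params.app_mm,
             "harmonic_rel_amp": params.harmonic_rel_amp,
             "has_harmonic": params.harmonic_rel_amp > 0,
             "angle_rad": float(angle), "scale_mm_per_px": params.scale_mm_per_px,
             "circular": params.circular, **artefacts}
    return ts, truth


def _narrowband_oscillator(rng: np.random.Generator, n: int, fs: float,
                           f0: float, bandwidth_hz: float = 1.2) -> np.ndarray:
    """Unit-RMS stochastic oscillator: white noise band-passed around f0.

    The random phase/envelope modulation is what makes two independent draws
    incoherent; two pure sinusoids at the same frequency would always show
    coherence 1 regardless of independence.  The ~1 Hz bandwidth matches the
    spectral width of physiological tremor peaks and gives the oscillator a
    correlation time below one analysis segment (1 s), the regime in which
    the segment-count-based coherence threshold is calibrated.
    """
    white = rng.normal(size=n + int(10 * fs))
    low = max(0.1, f0 - bandwidth_hz / 2)
    sos = sps.butter(2, [low, f0 + bandwidth_hz / 2], btype="band",
                     fs=fs, output="sos")
    x = sps.sosfilt(sos, white)[int(10 * fs):]   # drop the warm-up transient
    return x / np.std(x)


def simulate_bilateral(params: TremorSimParams, mixing: float,
                       seed: int | None = None
                       ) -> tuple[KeypointTimeSeries, KeypointTimeSeries, dict]:
    """Simulate both hands with controllable inter-limb coherence.

    Each hand's oscillator is ``mixing * shared + (1 - mixing) * independent``
    (re-normalised to equal marginal amplitude): ``mixing=0`` gives fully
    independent hands (the essential-tremor phenotype), ``mixing=1``
    identical drives (coherence 1 at the tremor frequency).
    """
    if not (0 <= mixing <= 1):
        raise ParameterError("mixing must lie in [0, 1]")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(params.duration_s * params.frame_rate))
    fs = params.frame_rate
    shared = _narrowband_oscillator(rng, n, fs, params.f0)
    a_rms_px = (params.app_mm / 2.0) / params.scale_mm_per_px / np.sqrt(2)

    out = []
    angle = (rng.uniform(0, 2 * np.pi) if params.angle_rad is None
             else params.angle_rad)
    axis = np.array([np.cos(angle), np.sin(angle)])
    for hand in ("left", "right"):
        own = _narrowband_oscillator(rng, n, fs, params.f0)
        mix = mixing * shared + (1 - mixing) * own
        norm = np.std(mix)
        osc = (mix / norm if norm > 0 else mix) * a_rms_px
        disp = np.outer(osc, axis)
        ts, artefacts = _assemble_keypoints(disp, params, rng, hand=hand)
        out.append(ts)
    truth = {"mixing": mixing, "f0": params.f0, "app_mm": params.app_mm,
             "angle_rad": float(angle)}
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# accelerometer simulator
# ---------------------------------------------------------------------------

def simulate_accel(f0: float, amp: float = 2.0, duration_s: float = 30.0,
                   noise_sd: float = 0.1, seed: int = 0,
                   sample_rate: float = 128.0,
                   bursts: list[tuple[float, float]] | None = None
                   ) -> tuple[AccelRecording, dict]:
    """Simulate a tri-axial wrist accelerometer recording at 128 Hz.

    One randomly chosen axis carries the tremor oscillation (``amp`` m/s^2
    zero-to-peak at ``f0``); another carries a constant gravity offset; all
    axes carry white noise.  ``bursts`` (time intervals in s) gate the
    oscillation on/off to emulate kinetic finger-to-nose trials, in which
    case the recording is tagged ``condition='kinetic'``.
    """
    if f0 >= sample_rate / 2:
        raise ParameterError("f0 must be below the Nyquist frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    osc_axis = int(rng.integers(3))
    gravity_axis = int(rng.integers(3))
    osc = amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    if bursts is not None:
        gate = np.zeros(n)
        for t0, t1 in bursts:
            gate[(t >= t0) & (t < t1)] = 1.0
        osc = osc * gate
    data = rng.normal(0.0, noise_sd, size=(3, n))
    data[osc_axis] += osc
    data[gravity_axis] += 9.81
    rec = AccelRecording(sample_rate=sample_rate, data=data, units="m/s2",
                         condition="kinetic" if bursts else "postural")
    truth = {"f0": f0, "amp": amp, "osc_axis": osc_axis,
             "gravity_axis": gravity_axis, "bursts": bursts}
    return rec, truth


# ---------------------------------------------------------------------------
# cohort simulator
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_cohort(params: CohortSimParams):
    """Simulate per-patient baseline kinematics and binary DBS response.

    Baseline features are truncated Gaussians (amplitudes >= 2 mm,
    frequencies in [2, 12] Hz); the poor/good label is Bernoulli under the
    logistic model ``P(poor) = sigmoid(beta0 + X @ beta)``; the post-DBS
    kinetic amplitude is ``pre * (1 - reduction)`` with the reduction drawn
    from the label's distribution inside the interval that keeps the label
    consistent with the residual/reduction binarization rule.  All-one-class
    cohorts are redrawn up to 100 times, then raise.

    Returns ``(records, truth)`` where ``records`` is a DataFrame with one
    row per patient and ``truth`` carries the generating coefficients.
    """
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    k = len(COHORT_FEATURES)
    # baseline kinetic amplitude is truncated at the 20 mm residual threshold:
    # DBS candidates have clinically relevant tremor, and below it the
    # binarization rule cannot represent a poor response at all, which would
    # truncate the generating logistic model
    lo = np.array([20.0, 2.0, 2.0, 2.0])
    hi = np.array([np.inf, np.inf, 12.0, 12.0])

    for _attempt in range(100):
        X = rng.normal(params.feature_means, params.feature_sds, size=(n, k))
        for j in range(k):
            bad = (X[:, j] < lo[j]) | (X[:, j] > hi[j])
            while bad.any():
                X[bad, j] = rng.normal(params.feature_means[j],
                                       params.feature_sds[j], size=bad.sum())
                bad = (X[:, j] < lo[j]) | (X[:, j] > hi[j])
        p_poor = _sigmoid(params.beta[0] + X @ params.beta[1:])
        poor = rng.random(n) < p_poor
        if poor.any() and (~poor).any():
            break
    else:
        raise QualityError("could not draw a two-class cohort in 100 attempts")

    pre = X[:, 0]
    residual_mm, reduction_frac = 20.0, 0.30
    reduction = np.empty(n)
    for i in range(n):
        if poor[i] and pre[i] < residual_mm:
            # a poor label is infeasible under the binarization rule for this
            # small a baseline amplitude; redraw the label (rarely sticks)
            for _ in range(100):
                poor[i] = rng.random() < p_poor[i]
                if not poor[i] or pre[i] >= residual_mm:
                    break
            if poor[i] and pre[i] < residual_mm:
                poor[i] = False
        mean, sd = params.reduction_poor if poor[i] else params.reduction_good
        for _ in range(100):
            r = rng.normal(mean, sd)
            post = pre[i] * (1 - r)
            is_poor = (post >= residual_mm) and (r <= reduction_frac)
            if is_poor == poor[i]:
                break
        else:
            # deterministic fallback inside the feasible interval
            r = (min(reduction_frac, 1 - residual_mm / pre[i]) / 2 if poor[i]
                 else max(mean, reduction_frac + 0.1))
        reduction[i] = r

    records = pd.DataFrame(X, columns=list(COHORT_FEATURES))
    records.insert(0, "patient_id", [f"P{i:03d}" for i in range(n)])
    records["post_amplitude_mm"] = pre * (1 - reduction)
    records["relative_reduction"] = reduction
    records["responder"] = np.where(poor, "poor", "good")
    truth = {"beta": params.beta.tolist(),
             "feature_names": list(COHORT_FEATURES),
             "prevalence_poor": float(poor.mean())}
    return records, truth
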