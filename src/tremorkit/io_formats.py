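"""Data containers, CSV readers/writers and report serialisation.

Everything downstream of this module is format-agnostic: keypoint series,
accelerometer recordings, calibration and pipeline configuration enter the
pipeline only through the types defined here.

Conventions
-----------
* Frames are 0-based; frame ``k`` occurs at time ``k / frame_rate``; all
  windows are half-open ``[t0, t1)``.
* Keypoint coordinates are image coordinates (origin top-left, y grows
  downward) in pixels, as emitted by common hand trackers.  The convention
  is irrelevant to amplitude/frequency after band-passing.
* Units are mandatory in file headers (px, mm, m/s2, g); values are never
  guessed.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class TremorKitError(Exception):
    """Base class for all validation/quality errors raised by the package."""


class FormatError(TremorKitError):
    """A file does not conform to the expected dialect."""


class ParameterError(TremorKitError):
    """An argument violates a precondition (Nyquist, sign, range ...)."""


class QualityError(TremorKitError):
    """Input data are formally valid but unusable (too many masked frames ...)."""


# ---------------------------------------------------------------------------
# landmark convention
# ---------------------------------------------------------------------------

#: Ordered names of the 21-point hand-landmark convention (wrist, then four
#: joints per digit ending at the fingertip).
HAND_LANDMARKS: tuple[str, ...] = (
    "wrist",
    "thumb_cmc", "thumb_mcp", "thumb_ip", "thumb_tip",
    "index_finger_mcp", "index_finger_pip", "index_finger_dip", "index_finger_tip",
    "middle_finger_mcp", "middle_finger_pip", "middle_finger_dip", "middle_finger_tip",
    "ring_finger_mcp", "ring_finger_pip", "ring_finger_dip", "ring_finger_tip",
    "pinky_mcp", "pinky_pip", "pinky_dip", "pinky_tip",
)

POSTURAL_LANDMARK = "middle_finger_tip"
KINETIC_LANDMARK = "index_finger_tip"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable constants of the analysis pipeline.

    Defaults follow the reference clinical pipeline: tracker points with
    confidence below 0.5 are discarded, jumps over 100 px are treated as
    tracking spikes, the tremor band-pass is 1-10 Hz, short-time spectra use
    1 s windows with 50 % overlap, and equivalence margins are 10 mm
    (amplitude) / 0.5 Hz (frequency).
    """

    confidence_threshold: float = 0.5
    spike_jump_px: float = 100.0
    bandpass_low: float = 1.0
    bandpass_high: float = 10.0
    filter_order: int = 4            # keypoint band-pass (Butterworth, zero-phase)
    accel_filter_order: int = 5      # accelerometer band-pass (Butterworth)
    stft_window_s: float = 1.0
    stft_overlap: float = 0.5
    alpha: float = 0.05
    sesoi_amplitude_mm: float = 10.0
    sesoi_frequency_hz: float = 0.5
    responder_residual_mm: float = 20.0
    responder_reduction_frac: float = 0.30
    rout_Q: float = 0.01
    # tremor band used for the coherence verdict (essential tremor: 4-8 Hz)
    tremor_band_low: float = 4.0
    tremor_band_high: float = 8.0
    # harmonic analysis
    harmonic_exclusion_hz: float = 1.0
    harmonic_prominence_frac: float = 0.05
    harmonic_window_s: float = 5.0
    # kinetic-burst envelope segmentation
    envelope_window_s: float = 0.5
    envelope_threshold_frac: float = 0.5
    envelope_percentile: float = 95.0
    segment_merge_gap_s: float = 0.25
    segment_min_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ParameterError("require 0 < bandpass_low < bandpass_high")
        if not (0 <= self.stft_overlap < 1):
            raise ParameterError("stft_overlap must be in [0, 1)")
        for name in ("confidence_threshold", "spike_jump_px", "stft_window_s",
                     "sesoi_amplitude_mm", "sesoi_frequency_hz",
                     "responder_residual_mm", "responder_reduction_frac"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must be in (0, 1)")
        if not (0 <= self.rout_Q < 1):
            raise ParameterError("rout_Q must be in [0, 1)")


def read_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key=value`` text file into a :class:`PipelineConfig`.

    Unknown keys raise :class:`FormatError`; missing keys keep their default.
    Lines starting with ``#`` and blank lines are ignored.
    """
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    kwargs: dict[str, float | int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"line {lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in fields:
            raise FormatError(f"line {lineno}: unknown config key {key!r}")
        kwargs[key] = int(value) if "int" in str(fields[key]) else float(value)
    return PipelineConfig(**kwargs)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = [f"{f.name}={getattr(cfg, f.name)!r}" for f in dataclasses.fields(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class KeypointTimeSeries:
    """Per-frame hand-landmark coordinates with confidences.

    ``coords`` has shape ``(n_frames, n_landmarks, n_axes)`` in px (2 or 3
    axes); ``confidence`` has shape ``(n_frames, n_landmarks)`` in [0, 1];
    ``missing`` flags (frame, landmark) cells whose coordinates are invalid.
    """

    frame_rate: float
    hand: str
    coords: np.ndarray
    confidence: np.ndarray
    landmark_names: tuple[str, ...] = HAND_LANDMARKS
    missing: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        if self.hand not in ("left", "right"):
            raise ParameterError(f"hand must be 'left' or 'right', got {self.hand!r}")
        if self.coords.ndim != 3 or self.coords.shape[2] not in (2, 3):
            raise ParameterError("coords must have shape (frames, landmarks, 2|3)")
        if self.confidence.shape != self.coords.shape[:2]:
            raise ParameterError("confidence shape must match coords[:2]")
        if len(set(self.landmark_names)) != len(self.landmark_names):
            raise ParameterError("landmark_names must be unique")
        if len(self.landmark_names) != self.coords.shape[1]:
            raise ParameterError("landmark_names length must match coords")
        finite_conf = self.confidence[np.isfinite(self.confidence)]
        if finite_conf.size and (finite_conf.min() < 0 or finite_conf.max() > 1):
            raise ParameterError("confidence values must lie in [0, 1]")
        if self.missing is None:
            self.missing = ~np.isfinite(self.coords).all(axis=2)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            self.missing |= ~np.isfinite(self.coords).all(axis=2)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_axes(self) -> int:
        return self.coords.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def landmark_index(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise ParameterError(
                f"landmark {name!r} not present in this series") from None


@dataclass
class AccelRecording:
    """Tri-axial wrist accelerometer recording at a uniform sample rate."""

    sample_rate: float
    data: np.ndarray            # shape (3, n_samples)
    units: str = "m/s2"
    side: str = "right"
    condition: str = "postural"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be > 0")
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise ParameterError("data must have shape (3, n_samples)")
        if self.units not in ("m/s2", "g"):
            raise ParameterError(f"units must be 'm/s2' or 'g', got {self.units!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class CalibrationInfo:
    """Pixel-to-metric scale and its provenance.

    ``source='ipd'`` means the scale is the participant's real interpupillary
    distance in mm divided by its apparent length in px on the video;
    ``source='board'`` a calibration-board-derived mm/px factor;
    ``source='none'`` leaves downstream outputs in px (flagged non-metric).
    """

    scale: float
    source: str = "none"
    ipd_mm: float | None = None
    ipd_px: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("ipd", "board", "none"):
            raise ParameterError("source must be 'ipd', 'board' or 'none'")
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")
        if self.source == "ipd":
            if not self.ipd_mm or not self.ipd_px:
                raise ParameterError("ipd source requires ipd_mm and ipd_px")
            if self.scale != self.ipd_mm / self.ipd_px:
                raise ParameterError("scale must equal ipd_mm / ipd_px")


UNCALIBRATED = CalibrationInfo(scale=1.0, source="none")


# ---------------------------------------------------------------------------
# keypoint CSV (long and wide dialects)
# ---------------------------------------------------------------------------

def _read_headers(path: Path) -> tuple[dict[str, str], str]:
    """Split ``#key=value`` header lines from the CSV body."""
    headers: dict[str, str] = {}
    body_lines: list[str] = []
    for raw in path.read_text().splitlines():
        if raw.startswith("#"):
            key, _, value = raw[1:].partition("=")
            headers[key.strip()] = value.strip()
        else:
            body_lines.append(raw)
    return headers, "\n".join(body_lines)


def read_keypoints(path: str | Path, dialect: str = "long") -> KeypointTimeSeries:
    """Read a keypoint CSV in the long or wide dialect.

    Long dialect: columns ``frame,landmark,x,y[,z],confidence`` with header
    lines ``#frame_rate=<Hz>`` and ``#hand=<left|right>``.  Wide dialect: one
    row per frame with per-landmark column groups ``<name>_x,<name>_y[,_z],
    <name>_conf``.  Rows with non-finite coordinates set the missing mask.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect not in ("long", "wide"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    headers, body = _read_headers(path)
    for required in ("frame_rate", "hand"):
        if required not in headers:
            raise FormatError(f"missing #{required}= header in {path}")
    frame_rate = float(headers["frame_rate"])
    hand = headers["hand"]
    df = pd.read_csv(io.StringIO(body), float_precision="round_trip")

    if dialect == "long":
        cols = list(df.columns)
        axes = ("x", "y", "z") if "z" in cols else ("x", "y")
        expected = ["frame", "landmark", *axes, "confidence"]
        if cols != expected:
            raise FormatError(f"long dialect expects columns {expected}, got {cols}")
        frames = df["frame"].to_numpy()
        landmarks = df["landmark"].astype(str)
        unknown = sorted(set(landmarks) - set(HAND_LANDMARKS))
        if unknown:
            raise FormatError(f"unknown landmark name(s): {', '.join(unknown)}")
        uniq_frames = np.unique(frames)
        if not np.array_equal(uniq_frames, np.arange(len(uniq_frames))):
            # also catches a non-monotone frame index within a landmark group
            raise FormatError("frame index must be 0-based and consecutive")
        per_lm = df.groupby("landmark", sort=False)["frame"]
        if any(not g.is_monotonic_increasing for _, g in per_lm):
            raise FormatError("non-monotone frame index")
        bad_conf = df.index[(df["confidence"] < 0) | (df["confidence"] > 1)]
        if len(bad_conf):
            raise FormatError(
                f"confidence outside [0,1] at data row {int(bad_conf[0]) + 1}")
        present = [n for n in HAND_LANDMARKS if n in set(landmarks)]
        n_frames, n_lm = len(uniq_frames), len(present)
        coords = np.full((n_frames, n_lm, len(axes)), np.nan)
        conf = np.zeros((n_frames, n_lm))
        lm_pos = {n: j for j, n in enumerate(present)}
        j = np.array([lm_pos[n] for n in landmarks])
        i = frames.astype(int)
        for a, ax in enumerate(axes):
            coords[i, j, a] = df[ax].to_numpy()
        conf[i, j] = df["confidence"].to_numpy()
        return KeypointTimeSeries(frame_rate=frame_rate, hand=hand, coords=coords,
                                  confidence=conf, landmark_names=tuple(present))

    # wide dialect
    if "frame" not in df.columns:
        raise FormatError("wide dialect requires a 'frame' column")
    if not df["frame"].is_monotonic_increasing:
        raise FormatError("non-monotone frame index")
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            names.append(col[:-2])
    unknown = sorted(set(names) - set(HAND_LANDMARKS))
    if unknown:
        raise FormatError(f"unknown landmark name(s): {', '.join(unknown)}")
    names = [n for n in HAND_LANDMARKS if n in names]
    has_z = any(f"{n}_z" in df.columns for n in names)
    axes = ("x", "y", "z") if has_z else ("x", "y")
    n_frames = len(df)
    coords = np.full((n_frames, len(names), len(axes)), np.nan)
    conf = np.zeros((n_frames, len(names)))
    for j, n in enumerate(names):
        for a, ax in enumerate(axes):
            coords[:, j, a] = df[f"{n}_{ax}"].to_numpy()
        conf[:, j] = df[f"{n}_conf"].to_numpy()
    if conf[np.isfinite(conf)].size and ((conf < 0) | (conf > 1)).any():
        row = int(np.argwhere((conf < 0) | (conf > 1))[0, 0]) + 1
        raise FormatError(f"confidence outside [0,1] at data row {row}")
    return KeypointTimeSeries(frame_rate=frame_rate, hand=hand, coords=coords,
                              confidence=conf, landmark_names=tuple(names))


def write_keypoints(ts: KeypointTimeSeries, path: str | Path,
                    dialect: str = "long") -> None:
    """Write a keypoint CSV; ``read_keypoints`` round-trips it bit-exactly.

    Floats are rendered at full precision (shortest repr), so read-back
    reproduces every value exactly.
    """
    path = Path(path)
    axes = ("x", "y", "z")[: ts.n_axes]
    header = f"#frame_rate={ts.frame_rate!r}\n#hand={ts.hand}\n"
    if dialect == "long":
        rows = []
        for j, name in enumerate(ts.landmark_names):
            block = {"frame": np.arange(ts.n_frames), "landmark": name}
            for a, ax in enumerate(axes):
                block[ax] = ts.coords[:, j, a]
            block["confidence"] = ts.confidence[:, j]
            rows.append(pd.DataFrame(block))
        df = (pd.concat(rows).sort_values(["frame", "landmark"],
                                          key=lambda s: s.map(
                                              {n: i for i, n in enumerate(ts.landmark_names)})
                                          if s.name == "landmark" else s)
              .reset_index(drop=True))
        df = df[["frame", "landmark", *axes, "confidence"]]
    elif dialect == "wide":
        data: dict[str, np.ndarray] = {"frame": np.arange(ts.n_frames)}
        for j, name in enumerate(ts.landmark_names):
            for a, ax in enumerate(axes):
                data[f"{name}_{ax}"] = ts.coords[:, j, a]
            data[f"{name}_conf"] = ts.confidence[:, j]
        df = pd.DataFrame(data)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    path.write_text(header + df.to_csv(index=False, float_format="%.17g"))


# ---------------------------------------------------------------------------
# accelerometer CSV
# ---------------------------------------------------------------------------

def read_accel(path: str | Path) -> AccelRecording:
    """Read an accelerometer CSV (``time_s,ax,ay,az``).

    Headers ``#units=``, ``#side=`` and ``#condition=`` are mandatory.  The
    sample rate is inferred from the timestamps; sampling must be uniform to
    within half a sample period.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    headers, body = _read_headers(path)
    for required in ("units", "side", "condition"):
        if required not in headers:
            raise FormatError(f"missing #{required}= header in {path}")
    df = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    if list(df.columns) != ["time_s", "ax", "ay", "az"]:
        raise FormatError("accelerometer CSV requires columns time_s,ax,ay,az")
    if len(df) < 2:
        raise FormatError("need at least 2 samples to infer the sample rate")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    period = float(np.median(dt))
    if period <= 0:
        raise FormatError("timestamps must be strictly increasing")
    if np.max(np.abs(dt - period)) >= period / 2:
        raise FormatError("non-uniform sampling (timestamp jitter > half a period)")
    data = df[["ax", "ay", "az"]].to_numpy().T
    return AccelRecording(sample_rate=1.0 / period, data=data,
                          units=headers["units"].replace("m/s^2", "m/s2"),
                          side=headers["side"], condition=headers["condition"])


def write_accel(rec: AccelRecording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.sample_rate
    df = pd.DataFrame({"time_s": t, "ax": rec.data[0],
                       "ay": rec.data[1], "az": rec.data[2]})
    header = f"#units={rec.units}\n#side={rec.side}\n#condition={rec.condition}\n"
    Path(path).write_text(header + df.to_csv(index=False, float_format="%.17g"))


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__type__": type(obj).__name__,
                **{k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_report(result, path: str | Path, fmt: str = "json") -> None:
    """Serialise a result record losslessly.

    JSON keeps every numeric field at full precision (shortest-repr floats
    round-trip exactly).  ``fmt='csv'`` is supported for coherence spectra:
    rows ``frequency_hz,coherence`` preceded by ``#threshold=`` / ``#L=`` /
    ``#significant=`` header lines.
    """
    path = Path(path)
    if fmt == "json":
        try:
            path.write_text(json.dumps(_jsonable(result), indent=2) + "\n")
        except OSError as exc:
            raise TremorKitError(f"cannot write {path}: {exc}") from exc
        return
    if fmt == "csv":
        if not hasattr(result, "freqs") or not hasattr(result, "coherence"):
            raise ParameterError("csv format is only defined for coherence results")
        header = (f"#threshold={result.threshold!r}\n#L={result.L}\n"
                  f"#significant={result.significant}\n")
        df = pd.DataFrame({"frequency_hz": result.freqs,
                           "coherence": result.coherence})
        path.write_text(header + df.to_csv(index=False, float_format="%.17g"))
        return
    raise ParameterError(f"unknown report format {fmt!r}")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
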