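"""Eye-tracking and face-tracking indices from raw per-session signals.

The eye-tracking pipeline reduces a binocular gaze stream to a single
magnitude signal, detects blinks as near-zero signal-loss runs, detects
fixations with a dispersion-threshold (I-DT) pass over the blink-free
samples, and summarises each session as four indices: mean blink duration,
blink frequency, mean fixation duration, fixation frequency.  The 21
face-tracking channels are summarised by their per-channel mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

#: The 21 facial channels exported by the tracking software, in report order.
FT_CHANNELS: tuple[str, ...] = (
    "brow_furrow",
    "brow_raise",
    "engagement",
    "lip_corner_depressor",
    "smile",
    "valence",
    "attention",
    "interocular_distance",
    "pitch",
    "yaw",
    "roll",
    "inner_brow_raise",
    "eye_closure",
    "nose_wrinkle",
    "upper_lip_raise",
    "lip_suck",
    "lip_press",
    "mouth_open",
    "chin_raise",
    "smirk",
    "lip_pucker",
)

#: The four eye-tracking indices, in report order.
ET_INDICES: tuple[str, ...] = (
    "blink_duration",
    "blink_frequency",
    "fixation_duration",
    "fixation_frequency",
)

#: All 25 per-session indices (4 eye-tracking + 21 face-tracking).
ALL_INDICES: tuple[str, ...] = ET_INDICES + FT_CHANNELS


@dataclass
class GazeRecording:
    """Timestamped binocular gaze stream for one session.

    Coordinates are in arbitrary but consistent screen/scene units; a
    sample where the signal was lost (blink) carries (0, 0) for both eyes.
    """

    t: np.ndarray
    xL: np.ndarray
    yL: np.ndarray
    xR: np.ndarray
    yR: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("xL", "yL", "xR", "yR"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} length {arr.size} != t length {self.t.size}")
            setattr(self, name, arr)
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class BlinkParams:
    """Thresholds for blink detection.

    ``magnitude_threshold`` is an absolute cutoff on the eye-magnitude
    signal; ``None`` means "derive it from the data" as 5% of the session's
    median magnitude (the near-zero cutoff is a per-recording visual
    judgement in practice, so the default is data-driven).  A run only
    counts as a blink if its duration strictly exceeds ``min_blink_ms``.
    """

    magnitude_threshold: float | None = None
    min_blink_ms: float = 20.0
    max_blink_ms: float = math.inf

    def __post_init__(self) -> None:
        if self.magnitude_threshold is not None and self.magnitude_threshold < 0:
            raise ValueError("magnitude_threshold must be >= 0")
        if self.min_blink_ms <= 0:
            raise ValueError("min_blink_ms must be > 0")


@dataclass(frozen=True)
class FixationParams:
    """I-DT parameters.

    ``dispersion_threshold``: maximum (max-min of x) + (max-min of y) of the
    averaged-eye position inside a fixation window, in coordinate units;
    ``None`` derives it as 1% of the session's coordinate range.
    ``min_fixation_ms``: minimum window duration to emit a fixation.
    """

    dispersion_threshold: float | None = None
    min_fixation_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.dispersion_threshold is not None and self.dispersion_threshold <= 0:
            raise ValueError("dispersion_threshold must be > 0")
        if self.min_fixation_ms <= 0:
            raise ValueError("min_fixation_ms must be > 0")


@dataclass(frozen=True)
class GazeEvent:
    """A blink or fixation: [start, end) in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start


BlinkEvent = GazeEvent
FixationEvent = GazeEvent


def eye_magnitude(gaze: GazeRecording) -> np.ndarray:
    """Per-sample eye-coordinate magnitude, ensemble-averaged over eyes.

    ``out[i] = (sqrt(xL^2 + yL^2) + sqrt(xR^2 + yR^2)) / 2``.  Samples
    where both eyes read (0, 0) -- signal loss -- map to 0.
    """
    left = np.hypot(gaze.xL, gaze.yL)
    right = np.hypot(gaze.xR, gaze.yR)
    return (left + right) / 2.0


def resolve_magnitude_threshold(magnitude: np.ndarray, params: BlinkParams) -> float:
    """Absolute blink threshold: configured value, or 5% of median magnitude."""
    if params.magnitude_threshold is not None:
        return params.magnitude_threshold
    if magnitude.size == 0:
        return 0.0
    return 0.05 * float(np.median(magnitude))


def detect_blinks(
    magnitude: np.ndarray,
    rate: float,
    params: BlinkParams = BlinkParams(),
) -> list[BlinkEvent]:
    """Blink events: maximal sub-threshold runs longer than ``min_blink_ms``.

    A blink ends at the first sample where the signal returns above the
    threshold; a run still open at the end of the recording is closed at
    the final sample.  Run duration is measured between those time points
    (``n_samples / rate`` for an interior run), and only runs with
    duration strictly greater than ``min_blink_ms`` are kept.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.size == 0:
        return []
    threshold = resolve_magnitude_threshold(magnitude, params)

    below = magnitude < threshold
    # run boundaries: starts where below goes False->True, ends True->False
    padded = np.concatenate(([False], below, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # index of first sample back above

    events: list[BlinkEvent] = []
    dt = 1.0 / rate
    for s, e in zip(starts, ends):
        e = min(e, magnitude.size - 1)  # run at the end: close at last sample
        if e == s:
            continue
        # duration in whole sample periods, avoiding float cancellation
        duration_ms = (e - s) / rate * 1000.0
        if params.min_blink_ms < duration_ms <= params.max_blink_ms:
            events.append(BlinkEvent(start=s * dt, end=e * dt))
    return events


def blink_indices(
    events: list[BlinkEvent], session_minutes: float
) -> tuple[float, float]:
    """(mean blink duration in ms, blinks per minute).

    An event-free session has frequency 0 and a NaN mean duration; the
    missing mean is imputed downstream with an explicit warning.
    """
    if session_minutes <= 0:
        raise ValueError("session_minutes must be positive")
    freq = len(events) / session_minutes
    if not events:
        return float("nan"), freq
    mean_ms = 1000.0 * float(np.mean([ev.duration for ev in events]))
    return mean_ms, freq


def detect_fixations(
    gaze: GazeRecording,
    params: FixationParams = FixationParams(),
    blink_params: BlinkParams = BlinkParams(),
) -> list[FixationEvent]:
    """Dispersion-threshold (I-DT) fixation detection on blink-free samples.

    Blink samples (sub-threshold magnitude) are excluded first; within each
    contiguous non-blink segment a window grows while the dispersion
    (max-min of x) + (max-min of y) of the averaged-eye position stays
    within the threshold, and is emitted as a fixation if it spans at
    least ``min_fixation_ms``.
    """
    magnitude = eye_magnitude(gaze)
    if magnitude.size == 0:
        return []
    blink_threshold = resolve_magnitude_threshold(magnitude, blink_params)
    valid = magnitude >= blink_threshold

    x = (gaze.xL + gaze.xR) / 2.0
    y = (gaze.yL + gaze.yR) / 2.0

    if params.dispersion_threshold is not None:
        dispersion = params.dispersion_threshold
    else:
        xv, yv = x[valid], y[valid]
        if xv.size == 0:
            return []
        coord_range = float(xv.max() - xv.min()) + float(yv.max() - yv.min())
        dispersion = 0.01 * coord_range if coord_range > 0 else 1e-9

    dt = 1.0 / gaze.rate
    min_len = max(1, int(math.ceil(params.min_fixation_ms / 1000.0 / dt)))

    events: list[FixationEvent] = []
    # contiguous valid segments
    padded = np.concatenate(([False], valid, [False]))
    edges = np.diff(padded.astype(np.int8))
    seg_starts = np.flatnonzero(edges == 1)
    seg_ends = np.flatnonzero(edges == -1)

    for seg_start, seg_end in zip(seg_starts, seg_ends):
        i = seg_start
        while i < seg_end:
            j = i + 1
            xmin = xmax = x[i]
            ymin = ymax = y[i]
            while j < seg_end:
                xmin, xmax = min(xmin, x[j]), max(xmax, x[j])
                ymin, ymax = min(ymin, y[j]), max(ymax, y[j])
                if (xmax - xmin) + (ymax - ymin) > dispersion:
                    break
                j += 1
            if j - i >= min_len:
                events.append(
                    FixationEvent(start=gaze.t[i], end=gaze.t[j - 1] + dt)
                )
                i = j
            else:
                i += 1
    return events


def fixation_indices(
    events: list[FixationEvent], session_minutes: float
) -> tuple[float, float]:
    """(mean fixation duration in ms, fixations per minute); mirrors blinks."""
    return blink_indices(events, session_minutes)


def ft_indices(series: dict[str, np.ndarray] | "object") -> dict[str, float]:
    """Per-channel arithmetic mean of the 21 facial-channel time series.

    Accepts a mapping of channel name -> samples (or a DataFrame with the
    channel columns); every channel must be non-empty and all channels the
    same length.
    """
    if hasattr(series, "columns"):  # DataFrame
        series = {c: np.asarray(series[c]) for c in FT_CHANNELS}
    lengths = {name: np.asarray(vals).size for name, vals in series.items()}
    missing = set(FT_CHANNELS) - set(lengths)
    if missing:
        raise ValueError(f"missing facial channels: {sorted(missing)}")
    if min(lengths.values()) == 0:
        raise ValueError("facial channels must be non-empty")
    if len(set(lengths.values())) > 1:
        raise ValueError("facial channels have mismatched lengths")
    return {name: float(np.mean(np.asarray(series[name], dtype=float))) for name in FT_CHANNELS}


def session_indices(
    gaze: GazeRecording,
    ft_series: dict[str, np.ndarray] | "object",
    session_minutes: float = 10.0,
    blink_params: BlinkParams = BlinkParams(),
    fixation_params: FixationParams = FixationParams(),
    impute_empty: bool = True,
) -> dict[str, float]:
    """All 25 indices for one session, as a name -> value mapping.

    Sessions with no blink (or fixation) events get frequency 0; the
    undefined mean duration is imputed as 0 with a warning when
    ``impute_empty`` is set, otherwise left as NaN.
    """
    magnitude = eye_magnitude(gaze)
    blinks = detect_blinks(magnitude, gaze.rate, blink_params)
    fixations = detect_fixations(gaze, fixation_params, blink_params)
    blink_dur, blink_freq = blink_indices(blinks, session_minutes)
    fix_dur, fix_freq = fixation_indices(fixations, session_minutes)
    out = {
        "blink_duration": blink_dur,
        "blink_frequency": blink_freq,
        "fixation_duration": fix_dur,
        "fixation_frequency": fix_freq,
    }
    for name, value in list(out.items()):
        if math.isnan(value) and impute_empty:
            warnings.warn(
                f"no events for {name}; imputing mean duration 0", stacklevel=2
            )
            out[name] = 0.0
    out.update(ft_indices(ft_series))
    return out
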