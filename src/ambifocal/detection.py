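"""Saccade and fixation detection from gaze traces.

Velocity and acceleration are estimated with Savitzky-Golay derivative
filters (10 ms window, polynomial order 2; 199 samples at the native
20 kHz coil sampling rate).  Candidate saccade periods are time segments
of supra-threshold eye speed (> 30 deg/s) containing supra-threshold
acceleration (> 8,000 deg/s^2); segments with implausible peak kinematics
(> 1,500 deg/s or > 120,000 deg/s^2), durations outside 5-100 ms, or gaze
shifts below 0.1 deg are rejected as artifacts.  Microsaccades are not
distinguished from saccades.  Periods between successive saccades become
fixations unless the gaze shifts within them exceed 1 deg, and events
initiated within the first 150 ms after stimulus onset are discarded as
stimulus-unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial import ConvexHull, QhullError

from .trace import GazeTrace

__all__ = [
    "DetectionConfig",
    "SaccadeEvent",
    "FixationEvent",
    "estimate_kinematics",
    "detect_saccades",
    "extract_fixations",
    "detect_events",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and filter settings for eye-event detection.

    The Savitzky-Golay window is specified in seconds and scaled to an odd
    number of samples at the trace's sampling rate, so traces sampled at
    rates other than 20 kHz behave equivalently.
    """

    sg_window: float = 0.010  # s
    sg_polyorder: int = 2
    vel_threshold: float = 30.0  # deg/s
    acc_threshold: float = 8_000.0  # deg/s^2
    max_peak_vel: float = 1_500.0  # deg/s
    max_peak_acc: float = 120_000.0  # deg/s^2
    min_duration: float = 0.005  # s
    max_duration: float = 0.100  # s
    min_amplitude: float = 0.1  # deg
    fixation_max_drift: float = 1.0  # deg
    onset_exclusion: float = 0.150  # s

    def __post_init__(self) -> None:
        for name in (
            "sg_window", "vel_threshold", "acc_threshold", "max_peak_vel",
            "max_peak_acc", "min_duration", "max_duration", "min_amplitude",
            "fixation_max_drift",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_duration >= self.max_duration:
            raise ValueError("min_duration must be below max_duration")

    def window_samples(self, sampling_rate: float) -> int:
        n = round(self.sg_window * sampling_rate)
        n = max(n, self.sg_polyorder + 1)
        if n % 2 == 0:
            n += 1
        return n


@dataclass
class SaccadeEvent:
    """A detected saccade.

    Amplitude is the Euclidean distance between the eye positions at the
    onset and the offset of the saccade period.
    """

    onset: float
    offset: float
    start_pos: tuple[float, float]
    end_pos: tuple[float, float]
    amplitude: float
    peak_velocity: float
    order_in_trial: int = 0

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class FixationEvent:
    """A detected fixation: the epoch between two successive saccades.

    The position is the mean gaze position over the fixation period.
    """

    onset: float
    offset: float
    position: tuple[float, float]
    duration: float
    order_in_trial: int = 0


def estimate_kinematics(
    trace: GazeTrace, cfg: DetectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eye speed and acceleration magnitude via Savitzky-Golay derivatives.

    Returns ``(speed, accel, valid)`` aligned to the trace samples: speed
    is the Euclidean norm of the per-axis first derivatives (deg/s), accel
    the norm of the second derivatives (deg/s^2).  ``valid`` flags the
    interior samples where the filter window is complete; the half-window
    edge samples are excluded from segment formation.
    """
    cfg = cfg or DetectionConfig()
    win = cfg.window_samples(trace.sampling_rate)
    if len(trace) < win:
        raise ValueError(f"trace has {len(trace)} samples but the filter needs {win}")
    delta = 1.0 / trace.sampling_rate
    vx = savgol_filter(trace.x, win, cfg.sg_polyorder, deriv=1, delta=delta)
    vy = savgol_filter(trace.y, win, cfg.sg_polyorder, deriv=1, delta=delta)
    ax = savgol_filter(trace.x, win, cfg.sg_polyorder, deriv=2, delta=delta)
    ay = savgol_filter(trace.y, win, cfg.sg_polyorder, deriv=2, delta=delta)
    speed = np.hypot(vx, vy)
    accel = np.hypot(ax, ay)
    valid = np.zeros(len(trace), dtype=bool)
    half = win // 2
    valid[half : len(trace) - half] = True
    return speed, accel, valid


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) index pairs, stop inclusive."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_stops = np.flatnonzero(d == -1) - 1
    return list(zip(run_starts.tolist(), run_stops.tolist()))


def detect_saccades(
    speed: np.ndarray,
    accel: np.ndarray,
    trace: GazeTrace,
    cfg: DetectionConfig | None = None,
    valid: np.ndarray | None = None,
) -> list[SaccadeEvent]:
    """Find saccade periods from the kinematic series.

    Candidate periods are maximal runs of supra-threshold speed whose peak
    acceleration magnitude also exceeds the acceleration threshold (the
    acceleration magnitude of any smooth saccade passes through zero at
    peak velocity, so requiring supra-threshold acceleration at every
    sample would split each saccade in two; the threshold is therefore
    applied to the segment's acceleration peak).  Candidates failing the
    artifact checks (peak kinematics caps, duration bounds, minimum gaze
    shift) are discarded.
    """
    cfg = cfg or DetectionConfig()
    if not (len(speed) == len(accel) == len(trace)):
        raise ValueError("kinematics must be computed on the trace's sample grid")
    mask = speed > cfg.vel_threshold
    if valid is not None:
        mask &= valid
    events: list[SaccadeEvent] = []
    for start, stop in _runs(mask):
        seg_speed = speed[start : stop + 1]
        seg_accel = accel[start : stop + 1]
        duration = trace.t[stop] - trace.t[start]
        dx = trace.x[stop] - trace.x[start]
        dy = trace.y[stop] - trace.y[start]
        amplitude = float(np.hypot(dx, dy))
        if seg_accel.max() < cfg.acc_threshold:
            continue
        if seg_speed.max() > cfg.max_peak_vel or seg_accel.max() > cfg.max_peak_acc:
            continue
        if duration < cfg.min_duration or duration > cfg.max_duration:
            continue
        if amplitude < cfg.min_amplitude:
            continue
        events.append(
            SaccadeEvent(
                onset=float(trace.t[start]),
                offset=float(trace.t[stop]),
                start_pos=(float(trace.x[start]), float(trace.y[start])),
                end_pos=(float(trace.x[stop]), float(trace.y[stop])),
                amplitude=amplitude,
                peak_velocity=float(seg_speed.max()),
            )
        )
    return events


def _max_displacement(x: np.ndarray, y: np.ndarray) -> float:
    """Diameter (max pairwise distance) of the gaze point set."""
    if len(x) < 2:
        return 0.0
    pts = np.column_stack([x, y])
    if len(pts) > 3:
        try:
            hull = pts[ConvexHull(pts).vertices]
        except QhullError:  # degenerate (e.g. collinear) point sets
            hull = _extreme_points(pts)
    else:
        hull = pts
    d = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


def _extreme_points(pts: np.ndarray) -> np.ndarray:
    """Extremes along axes and diagonals; exact for degenerate sets."""
    proj = np.column_stack(
        [pts[:, 0], pts[:, 1], pts[:, 0] + pts[:, 1], pts[:, 0] - pts[:, 1]]
    )
    idx = np.unique(np.concatenate([proj.argmin(axis=0), proj.argmax(axis=0)]))
    return pts[idx]


def extract_fixations(
    saccades: list[SaccadeEvent],
    trace: GazeTrace,
    cfg: DetectionConfig | None = None,
) -> tuple[list[SaccadeEvent], list[FixationEvent]]:
    """Fixations between saccades, with the stimulus-onset exclusions.

    Every inter-saccade interval, the leading interval from stimulus onset
    to the first saccade, and the trailing interval to the trace end
    becomes a fixation iff the maximum gaze displacement within it stays
    within the drift limit.  The leading fixation is treated as initiated
    before stimulus onset (it continues the pre-stimulus fixation), so the
    150 ms exclusion removes saccades and fixations whose onset falls
    strictly after stimulus onset but within the exclusion window.
    Returns the surviving saccades and fixations, re-indexed in time order.
    """
    cfg = cfg or DetectionConfig()
    t0 = trace.stimulus_onset
    saccades = sorted(saccades, key=lambda s: s.onset)
    for a, b in zip(saccades, saccades[1:]):
        if b.onset < a.offset:
            raise ValueError("saccade periods overlap")
    saccades = [s for s in saccades if s.onset >= t0]

    bounds: list[tuple[float, float]] = []
    edges = [t0] + [tt for s in saccades for tt in (s.onset, s.offset)] + [float(trace.t[-1])]
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi > lo:
            bounds.append((lo, hi))

    fixations: list[FixationEvent] = []
    for lo, hi in bounds:
        sel = (trace.t >= lo) & (trace.t <= hi)
        if sel.sum() < 2:
            continue
        if _max_displacement(trace.x[sel], trace.y[sel]) > cfg.fixation_max_drift:
            continue
        fixations.append(
            FixationEvent(
                onset=lo,
                offset=hi,
                position=(float(trace.x[sel].mean()), float(trace.y[sel].mean())),
                duration=hi - lo,
            )
        )

    cut = t0 + cfg.onset_exclusion
    saccades = [s for s in saccades if not (t0 < s.onset < cut)]
    fixations = [f for f in fixations if not (t0 < f.onset < cut)]
    for i, s in enumerate(saccades, start=1):
        s.order_in_trial = i
    for i, f in enumerate(fixations, start=1):
        f.order_in_trial = i
    return saccades, fixations


def detect_events(
    trace: GazeTrace, cfg: DetectionConfig | None = None
) -> tuple[list[SaccadeEvent], list[FixationEvent]]:
    """Full detection pipeline: kinematics, saccades, fixations."""
    cfg = cfg or DetectionConfig()
    speed, accel, valid = estimate_kinematics(trace, cfg)
    saccades = detect_saccades(speed, accel, trace, cfg, valid)
    return extract_fixations(saccades, trace, cfg)
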