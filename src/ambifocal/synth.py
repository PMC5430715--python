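"""Synthetic free-viewing trials: ground-truth events and rendered traces.

The generator bridges the abstract saccade-sequence model to spatial gaze
data.  A trial is simulated in three stages:

1. the two-mode Markov model produces fixation labels (object/background)
   and the true switch step (:mod:`ambifocal.model`);
2. labels are spatialized on a stimulus layout: intra-object saccades land
   on a fresh point within the same object, trans-object saccades on a
   uniformly chosen different object, background fixations on a point
   1.5-3 deg away from every object center; fixation durations are
   gamma-distributed with a mean that grows linearly over the trial,
   emulating the empirical increase of fixation duration with viewing
   time;
3. the event sequence is rendered as a uniformly sampled gaze trace:
   stationary (plus optional white position noise) during fixations, and a
   raised-cosine (cosine-bell) velocity profile during saccades whose
   duration follows a main-sequence rule
   ``duration = intercept + slope * amplitude``.

The renderer is the inverse of the event-detection stage, which makes
noise-free round trips (render then detect) an exact test of the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelParams, simulate_trials
from .stimuli import StimulusLayout
from .trace import GazeTrace

__all__ = [
    "TrialGroundTruth",
    "RenderConfig",
    "generate_trial_events",
    "render_gaze_trace",
]

BACKGROUND = "background"

#: Background fixations land with a nearest-object-center distance inside
#: this band: unambiguously off-object under the 1.5 deg rule yet close
#: enough to be spatially plausible.
BACKGROUND_DISTANCE_BAND = (1.5, 3.0)


@dataclass
class TrialGroundTruth:
    """Ground truth of one synthetic trial.

    ``fixation_labels`` holds the realized label of each fixation: an
    object id (int) or ``"background"``.  ``true_switch_step`` is the
    1-based order of the first late-mode saccade, or ``None`` if the
    ambient-to-focal switch did not occur within the trial.
    """

    fixation_positions: np.ndarray  # (n_fix, 2) deg
    fixation_durations: np.ndarray  # (n_fix,) s
    fixation_labels: list
    saccade_list: list[tuple[int, int]]
    true_switch_step: int | None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.fixation_labels)
        if self.fixation_positions.shape != (n, 2):
            raise ValueError("fixation_positions must be (n_fix, 2)")
        if len(self.fixation_durations) != n:
            raise ValueError("one duration per fixation required")
        if len(self.saccade_list) != n - 1:
            raise ValueError("#saccades must equal #fixations - 1")

    @property
    def n_fixations(self) -> int:
        return len(self.fixation_labels)

    @property
    def saccade_amplitudes(self) -> np.ndarray:
        d = np.diff(self.fixation_positions, axis=0)
        return np.hypot(d[:, 0], d[:, 1])


@dataclass(frozen=True)
class RenderConfig:
    """Rendering constants for synthetic gaze traces.

    The main-sequence constants are chosen so that every saccade of
    amplitude >= 0.5 deg exceeds the detection thresholds (peak velocity
    30 deg/s, peak acceleration 8,000 deg/s^2) while staying below the
    artifact-rejection caps (1,500 deg/s, 120,000 deg/s^2) up to 15 deg:
    for a raised-cosine profile of amplitude A and duration D the peak
    velocity is 2A/D and the peak acceleration 2*pi*A/D^2.
    """

    sampling_rate: float = 20_000.0
    position_noise_sd: float = 0.0
    saccade_duration_intercept: float = 0.012
    saccade_duration_slope: float = 0.0012
    pre_stimulus_fixation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be >= 0")

    def saccade_duration(self, amplitude: float | np.ndarray):
        return self.saccade_duration_intercept + self.saccade_duration_slope * np.asarray(
            amplitude
        )


def _point_in_object(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    previous: np.ndarray | None,
    min_step: float,
    max_attempts: int = 1000,
) -> np.ndarray:
    for _ in range(max_attempts):
        r = radius * np.sqrt(rng.random())
        phi = rng.uniform(0, 2 * np.pi)
        p = center + r * np.array([np.cos(phi), np.sin(phi)])
        if previous is None or np.hypot(*(p - previous)) >= min_step:
            return p
    raise RuntimeError("could not draw an object point satisfying the step size")


def _point_on_background(
    rng: np.random.Generator,
    layout: StimulusLayout,
    previous: np.ndarray | None,
    min_step: float,
    max_attempts: int = 10_000,
) -> np.ndarray:
    lo, hi = BACKGROUND_DISTANCE_BAND
    centers = layout.centers
    for _ in range(max_attempts):
        p = np.array(
            [
                rng.uniform(-layout.width / 2, layout.width / 2),
                rng.uniform(-layout.height / 2, layout.height / 2),
            ]
        )
        d = np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1]).min()
        if lo < d <= hi and (previous is None or np.hypot(*(p - previous)) >= min_step):
            return p
    raise RuntimeError("could not draw a background point in the distance band")


def generate_trial_events(
    params: ModelParams,
    layout: StimulusLayout,
    seed: int | np.random.Generator = 0,
    duration_base: float = 0.15,
    duration_slope: float = 0.04,
    duration_shape: float = 10.0,
    min_duration: float = 0.05,
    min_saccade_amplitude: float = 0.5,
) -> TrialGroundTruth:
    """Simulate one trial of the model and spatialize it on a layout.

    ``duration_base`` and ``duration_slope`` set the linearly increasing
    mean fixation duration (seconds, seconds per second of trial time);
    individual durations are gamma draws with shape ``duration_shape``,
    floored at ``min_duration``.  Consecutive fixation positions are kept
    at least ``min_saccade_amplitude`` apart (default 0.5 deg, the lower
    edge of the renderer's detectability guarantee) so every generated
    saccade is detectable.
    """
    if layout.n_objects < 2:
        raise ValueError("layout must contain at least 2 objects for trans saccades")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else None

    sim = simulate_trials(params, 1, rng)
    objects_putative = sim["objects"][0]  # two-object world ids (1/2)
    background = sim["background"][0]
    switch = int(sim["switch_step"][0])

    by_id = {o.id: o for o in layout.objects}
    ids = sorted(by_id)
    # map the abstract two-object alternation onto the layout: keep the
    # current object on intra steps, move to a uniformly chosen different
    # object whenever the putative identity changes
    current = ids[0]
    actual_ids = [current]
    for j in range(1, len(objects_putative)):
        if objects_putative[j] != objects_putative[j - 1]:
            current = rng.choice([i for i in ids if i != current])
        actual_ids.append(current)

    n_fix = params.n_fix
    positions = np.empty((n_fix, 2))
    labels: list = []
    prev: np.ndarray | None = None
    for j in range(n_fix):
        if background[j]:
            p = _point_on_background(rng, layout, prev, min_saccade_amplitude)
            labels.append(BACKGROUND)
        else:
            obj = by_id[actual_ids[j]]
            p = _point_in_object(
                rng, np.array([obj.x, obj.y]), obj.radius, prev, min_saccade_amplitude
            )
            labels.append(obj.id)
        positions[j] = p
        prev = p

    # gamma durations with linearly increasing mean over elapsed trial time
    durations = np.empty(n_fix)
    elapsed = 0.0
    for j in range(n_fix):
        mean = duration_base + duration_slope * elapsed
        d = rng.gamma(duration_shape, mean / duration_shape)
        durations[j] = max(d, min_duration)
        elapsed += durations[j]

    return TrialGroundTruth(
        fixation_positions=positions,
        fixation_durations=durations,
        fixation_labels=labels,
        saccade_list=[(j, j + 1) for j in range(n_fix - 1)],
        true_switch_step=switch if switch > 0 else None,
        seed=seed_val,
    )


def _raised_cosine_fraction(u: np.ndarray) -> np.ndarray:
    """Fraction of the displacement completed at normalized time u in [0, 1].

    The velocity profile is the cosine bell v(u) ~ 1 - cos(2 pi u), whose
    displacement integral is u - sin(2 pi u) / (2 pi); peak velocity is
    twice the mean velocity.
    """
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def render_gaze_trace(
    truth: TrialGroundTruth,
    cfg: RenderConfig,
    seed: int | np.random.Generator | None = None,
) -> GazeTrace:
    """Render ground-truth events as a uniformly sampled gaze trace.

    The trace starts with the pre-stimulus fixation held at the first
    fixation position; stimulus onset is at ``cfg.pre_stimulus_fixation``
    seconds.  Fixations are stationary epochs; saccades move along the
    straight line between fixation positions with a raised-cosine velocity
    profile.  White Gaussian position noise of ``cfg.position_noise_sd``
    is added to every sample.
    """
    if np.any(truth.fixation_durations <= 0):
        raise ValueError("all fixation durations must be positive")
    fs = cfg.sampling_rate
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )

    amplitudes = truth.saccade_amplitudes
    sac_durations = np.atleast_1d(cfg.saccade_duration(amplitudes))
    if len(amplitudes) and round(sac_durations.min() * fs) < 5:
        raise ValueError(
            f"sampling rate {fs} Hz yields fewer than 5 samples for the "
            f"shortest saccade ({sac_durations.min() * 1e3:.1f} ms)"
        )

    chunks: list[np.ndarray] = []

    def hold(position: np.ndarray, duration: float) -> None:
        n = round(duration * fs)
        if n > 0:
            chunks.append(np.tile(position, (n, 1)))

    def saccade(p0: np.ndarray, p1: np.ndarray, duration: float) -> None:
        n = round(duration * fs)
        u = (np.arange(n) + 1) / n
        frac = _raised_cosine_fraction(u)
        chunks.append(p0 + frac[:, None] * (p1 - p0))

    pos = truth.fixation_positions
    hold(pos[0], cfg.pre_stimulus_fixation + truth.fixation_durations[0])
    for j in range(len(amplitudes)):
        saccade(pos[j], pos[j + 1], float(sac_durations[j]))
        hold(pos[j + 1], truth.fixation_durations[j + 1])

    xy = np.concatenate(chunks, axis=0)
    if cfg.position_noise_sd > 0:
        xy = xy + rng.normal(0.0, cfg.position_noise_sd, xy.shape)
    t = np.arange(len(xy)) / fs
    return GazeTrace(
        t=t,
        x=xy[:, 0],
        y=xy[:, 1],
        sampling_rate=fs,
        stimulus_onset=cfg.pre_stimulus_fixation,
    )
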