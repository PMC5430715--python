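"""Uniformly sampled gaze traces in degrees of visual angle."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GazeTrace"]


@dataclass
class GazeTrace:
    """Gaze position samples ``(t, x, y)`` on a uniform time grid.

    ``t`` is in seconds and strictly increasing with a constant step of
    ``1 / sampling_rate`` (to within 1 ns); ``x`` and ``y`` are horizontal
    and vertical eye position in degrees.  ``stimulus_onset`` marks the
    time of stimulus-image onset within the trace (samples before it
    belong to the pre-stimulus central fixation).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_rate: float
    stimulus_onset: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("a gaze trace needs at least two samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > 1e-9:
            raise ValueError("time stamps must be uniform at 1 / sampling_rate")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])
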