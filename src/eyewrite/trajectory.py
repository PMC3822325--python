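"""Core in-memory containers for eye-written trajectories and their features.

A recording session yields a uniformly sampled gaze record (position plus
pupil diameter).  The deterministic front end summarizes each record as a
short sequence of *via-points* — samples where the horizontal or vertical
gaze velocity crosses zero, plus the trajectory endpoints — together with a
handful of auxiliary scalars (overall size, high-frequency band energy of
the velocity signal, pupil statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawTrajectory",
    "KinematicTrajectory",
    "ViaPoint",
    "AuxFeatures",
    "DegenerateTrajectoryWarning",
]


class DegenerateTrajectoryWarning(UserWarning):
    """Raised as a warning when saccade trimming would destroy a trajectory."""


@dataclass(frozen=True)
class RawTrajectory:
    """Uniformly sampled gaze record ``(t, x, y, d)``.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing, nominally uniform
        (75 Hz in the reference apparatus).
    x, y : array of float
        Gaze position in screen pixels (mathematical convention: y up).
    d : array of float
        Pupil diameter in device units relative to the calibration baseline
        (0 = diameter during calibration).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = self.t.size
        if n < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not all(getattr(self, k).size == n for k in ("x", "y", "d")):
            raise ValueError("t, x, y, d must have equal length")
        if not all(np.isfinite(getattr(self, k)).all() for k in ("t", "x", "y", "d")):
            raise ValueError("trajectory contains non-finite values")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.max(dt) - np.min(dt) > 0.01 * np.mean(dt):
            raise ValueError("sampling interval varies by more than 1%")

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        """Mean sampling interval in seconds."""
        return float(np.mean(np.diff(self.t)))

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class KinematicTrajectory:
    """Smoothed trajectory with per-sample velocities and acceleration.

    Velocities are in pixels/s; ``accel`` is the magnitude of the
    finite-difference derivative of the velocity vector expressed in
    pixels/sample², the unit in which the saccade-trimming threshold is
    stated.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    accel: np.ndarray
    d: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.x)
        if any(len(getattr(self, k)) != n for k in ("t", "y", "vx", "vy", "accel")):
            raise ValueError("all kinematic arrays must share one length")
        if np.any(np.asarray(self.accel) < 0):
            raise ValueError("accelerations are magnitudes and must be >= 0")

    def __len__(self) -> int:
        return len(self.x)

    def slice(self, start: int, stop: int) -> "KinematicTrajectory":
        d = self.d[start:stop] if self.d is not None else None
        return KinematicTrajectory(
            t=self.t[start:stop],
            x=self.x[start:stop],
            y=self.y[start:stop],
            vx=self.vx[start:stop],
            vy=self.vy[start:stop],
            accel=self.accel[start:stop],
            d=d,
        )


@dataclass(frozen=True)
class ViaPoint:
    """One four-dimensional via-point.

    ``dx, dy`` are the displacement (pixels) since the previously kept
    via-point — ``(0, 0)`` for the first one, since eye writing has no
    absolute reference frame — and ``vx, vy`` are the instantaneous
    velocities (pixels/s) at the via-point sample.
    """

    dx: float
    dy: float
    vx: float
    vy: float
    index: int  # 1-based ordinal within the sequence

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("via-point ordinals are 1-based")


@dataclass(frozen=True)
class AuxFeatures:
    """Auxiliary whole-trajectory features.

    ``sx, sy``: bounding-box width and height in pixels; ``a``: spectral
    energy of the velocity signal above the pursuit/tremor cutoff
    frequency, in (px/s)² (mean-square convention, so Parseval holds);
    ``mu_p, sigma_p``: mean and standard deviation of the pupil diameter
    relative to calibration.
    """

    sx: float
    sy: float
    a: float
    mu_p: float
    sigma_p: float

    def __post_init__(self) -> None:
        if self.sx < 0 or self.sy < 0:
            raise ValueError("trajectory extent cannot be negative")
        if self.a < 0:
            raise ValueError("spectral energy cannot be negative")
        if self.sigma_p < 0:
            raise ValueError("pupil SD cannot be negative")
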