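"""Deterministic front end: from raw gaze records to via-points and features.

The processing chain is: binomial smoothing of positions, finite-difference
velocities (themselves smoothed), acceleration-threshold trimming of
intrusive saccades at trajectory boundaries, via-point extraction at
velocity zero crossings, and auxiliary feature computation (size, spectral
band energy, pupil statistics).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import comb

from .trajectory import (
    AuxFeatures,
    DegenerateTrajectoryWarning,
    KinematicTrajectory,
    RawTrajectory,
    ViaPoint,
)

__all__ = [
    "binomial_smooth",
    "finite_difference_velocity",
    "kinematics",
    "trim_intrusive_saccades",
    "extract_via_points",
    "compute_aux_features",
    "preprocess",
]


def binomial_smooth(series: Sequence[float], order: int) -> np.ndarray:
    """Convolve a series with the normalized binomial kernel of a given order.

    The kernel has ``order + 1`` taps proportional to the binomial
    coefficients ``C(order, k)``; its DC gain is exactly 1, so constants are
    preserved.  Boundaries use edge-reflection (symmetric) padding, which
    keeps output length equal to input length and avoids endpoint shrinkage.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if order < 0:
        raise ValueError("filter order must be non-negative")
    if order == 0:
        return series.copy()
    kernel = comb(order, np.arange(order + 1), exact=False)
    kernel /= kernel.sum()
    return ndimage.convolve1d(series, kernel, mode="reflect")


def finite_difference_velocity(positions: Sequence[float], dt: float) -> np.ndarray:
    """Per-sample velocity: central differences inside, one-sided at the ends.

    Exact for affine signals; second-order accurate (exact for quadratics at
    interior samples).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(positions, dt)


def kinematics(raw: RawTrajectory, binomial_order: int = 20) -> KinematicTrajectory:
    """Smooth a raw record and derive velocities and acceleration magnitude.

    Positions are binomially smoothed, velocities are finite differences of
    the smoothed positions and are smoothed again with the same filter
    (both position and velocity signals are filtered).  Acceleration is the
    magnitude of the per-sample velocity increment, in pixels/sample² — the
    unit of the saccade-trimming threshold.
    """
    dt = raw.dt
    x = binomial_smooth(raw.x, binomial_order)
    y = binomial_smooth(raw.y, binomial_order)
    vx = binomial_smooth(finite_difference_velocity(x, dt), binomial_order)
    vy = binomial_smooth(finite_difference_velocity(y, dt), binomial_order)
    # per-sample velocity (px/sample), then per-sample acceleration magnitude
    ax = np.gradient(vx * dt)
    ay = np.gradient(vy * dt)
    accel = np.hypot(ax, ay)
    return KinematicTrajectory(t=raw.t, x=x, y=y, vx=vx, vy=vy, accel=accel, d=raw.d)


def trim_intrusive_saccades(
    traj: KinematicTrajectory,
    threshold: float = 0.4,
    head: int = 30,
    tail: int = 5,
) -> KinematicTrajectory:
    """Remove saccade-contaminated samples at trajectory boundaries.

    Within the first ``head`` samples, if any sample's acceleration exceeds
    ``threshold`` (px/sample²), everything up to and including the last such
    sample is deleted; symmetrically, within the last ``tail`` samples,
    everything from the first offending sample onward is deleted.  The scans
    repeat until no offending sample remains in either window (a fixpoint,
    which makes the operation idempotent).  If a deletion would leave fewer
    than 2 samples the trajectory is returned as-is and a
    :class:`DegenerateTrajectoryWarning` is emitted.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    out = traj
    while True:
        n = len(out)
        window = out.accel[: min(head, n)]
        bad = np.flatnonzero(window > threshold)
        if bad.size == 0:
            break
        start = int(bad[-1]) + 1
        if n - start < 2:
            warnings.warn(
                "head trimming would leave < 2 samples; trajectory kept untrimmed",
                DegenerateTrajectoryWarning,
            )
            return out
        out = out.slice(start, n)
    while True:
        n = len(out)
        w = min(tail, n)
        window = out.accel[n - w :]
        bad = np.flatnonzero(window > threshold)
        if bad.size == 0:
            break
        stop = n - w + int(bad[0])
        if stop < 2:
            warnings.warn(
                "tail trimming would leave < 2 samples; trajectory kept untrimmed",
                DegenerateTrajectoryWarning,
            )
            return out
        out = out.slice(0, stop)
    return out


def _zero_crossing_candidates(v: np.ndarray) -> list[int]:
    """Indices where a velocity signal crosses or touches zero.

    A crossing between samples i and i+1 contributes the sample with the
    smaller absolute velocity; an exact zero contributes its own sample.
    """
    out: list[int] = []
    for i in range(v.size - 1):
        if v[i] == 0.0:
            out.append(i)
        elif np.sign(v[i]) != np.sign(v[i + 1]):
            out.append(i if abs(v[i]) <= abs(v[i + 1]) else i + 1)
    if v.size and v[-1] == 0.0:
        out.append(v.size - 1)
    return out


def extract_via_points(
    traj: KinematicTrajectory,
    max_count: int = 15,
    min_sep: float = 2.0,
) -> list[ViaPoint]:
    """Summarize a trajectory as at most ``max_count`` via-points.

    Candidates are the first sample, every sample where the x- or
    y-velocity crosses zero, and the last sample, in temporal order.  A
    candidate is rejected when **both** its |x| and |y| distances to the
    previously kept via-point fall below ``min_sep`` pixels (this removes
    superfluous via-points along plateaus); the final sample is always
    kept.  The first via-point carries displacement (0, 0); subsequent ones
    carry the displacement since the preceding kept via-point.
    """
    n = len(traj)
    if n < 2:
        raise ValueError("need at least 2 samples to extract via-points")
    cand = {0, n - 1}
    cand.update(_zero_crossing_candidates(traj.vx))
    cand.update(_zero_crossing_candidates(traj.vy))
    ordered = sorted(cand)

    kept: list[int] = [ordered[0]]
    for i in ordered[1:]:
        if i == n - 1:
            kept.append(i)
            break
        if (
            abs(traj.x[i] - traj.x[kept[-1]]) < min_sep
            and abs(traj.y[i] - traj.y[kept[-1]]) < min_sep
        ):
            continue
        kept.append(i)
    kept = kept[:max_count]

    vps: list[ViaPoint] = []
    for k, i in enumerate(kept):
        if k == 0:
            dx = dy = 0.0
        else:
            dx = float(traj.x[i] - traj.x[kept[k - 1]])
            dy = float(traj.y[i] - traj.y[kept[k - 1]])
        vps.append(
            ViaPoint(dx=dx, dy=dy, vx=float(traj.vx[i]), vy=float(traj.vy[i]), index=k + 1)
        )
    return vps


def _band_power(v: np.ndarray, f0: float, sample_rate: float) -> float:
    """Mean-square power of ``v`` carried by frequencies strictly above f0.

    One-sided periodogram with rectangular window, normalized so the sum
    over all frequencies equals ``mean(v**2)`` (discrete Parseval).
    """
    n = v.size
    spec = np.fft.rfft(v)
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return float(power[freqs > f0].sum())


def compute_aux_features(
    traj: KinematicTrajectory,
    pupil: Sequence[float] | None = None,
    f0: float = 2.6,
    sample_rate: float = 75.0,
) -> AuxFeatures:
    """Whole-trajectory features: extent, band energy, pupil statistics.

    ``a`` is the summed power of the x- and y-velocity spectra above the
    cutoff ``f0`` separating smooth pursuit from high-frequency components
    (undetected saccades, ocular microtremor).
    """
    if sample_rate <= 2.0 * f0:
        raise ValueError("sample rate must exceed 2*f0 to resolve the band above f0")
    if pupil is None:
        pupil = traj.d
    pupil = np.asarray(pupil, dtype=float)
    a = _band_power(np.asarray(traj.vx), f0, sample_rate) + _band_power(
        np.asarray(traj.vy), f0, sample_rate
    )
    return AuxFeatures(
        sx=float(np.max(traj.x) - np.min(traj.x)),
        sy=float(np.max(traj.y) - np.min(traj.y)),
        a=a,
        mu_p=float(np.mean(pupil)),
        sigma_p=float(np.std(pupil)),
    )


def preprocess(
    raw: RawTrajectory,
    binomial_order: int = 20,
    accel_threshold: float = 0.4,
    trim_head: int = 30,
    trim_tail: int = 5,
    max_via_points: int = 15,
    min_sep: float = 2.0,
    f0: float = 2.6,
) -> tuple[list[ViaPoint], AuxFeatures]:
    """Full deterministic pipeline from a raw record to (via-points, features)."""
    kin = kinematics(raw, binomial_order)
    kin = trim_intrusive_saccades(kin, accel_threshold, trim_head, trim_tail)
    vps = extract_via_points(kin, max_via_points, min_sep)
    aux = compute_aux_features(kin, kin.d, f0, raw.sample_rate)
    return vps, aux
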