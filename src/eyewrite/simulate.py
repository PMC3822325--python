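"""Seedable generator of eye-writing-like labeled trajectories.

Real eye-written cursive letters are smooth-pursuit traces contaminated by
pursuit noise, movement-initiation saccades, and high-frequency oscillation
(ocular microtremor), with a pupil-diameter channel recorded alongside.
The generator emulates exactly those ingredients: a cubic-spline stroke
through a template's control points, additive Gaussian pursuit noise, an
optional sinusoidal high-frequency component, an optional ballistic
initiation saccade prepended to the trace (so boundary trimming has
something to remove), and a noisy pupil series.

A three-level motor-impairment manipulation can be applied to any
trajectory: spatial shrinking (scale 4/5 at level 2, 1/2 at level 3), an
added sinusoidal tremor of growing amplitude, a raised mean pupil diameter
and reduced pupil variability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .trajectory import RawTrajectory

__all__ = [
    "LetterTemplate",
    "GeneratorConfig",
    "LabeledTrajectory",
    "curated_templates",
    "procedural_template",
    "template_set",
    "generate_trajectory",
    "simulate_disability",
    "generate_database",
]


@dataclass(frozen=True)
class LetterTemplate:
    """A stylized single-stroke symbol: ordered 2-D control points in pixels."""

    symbol: str
    points: np.ndarray  # (m, 2)
    duration: float = 2.0  # nominal tracing time, seconds

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError("a template needs >= 3 two-dimensional control points")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """All stochastic ingredients of trajectory generation, with defaults.

    Noise magnitudes are in pixels, frequencies in Hz (and must stay below
    the Nyquist frequency of the sample rate).  The disability manipulation
    parameters give, per level, the spatial scale factor, the tremor
    amplitude added on both axes, and the pupil mean shift / SD factor.
    """

    sample_rate: float = 75.0
    pursuit_noise_sd: float = 0.8
    omt_amplitude: float = 0.3
    omt_freq: float = 18.0
    saccade_prob: float = 0.3
    saccade_amplitude: float = 40.0
    pupil_baseline: float = 0.1
    pupil_noise_sd: float = 1.0
    tremor_freq: float = 6.0
    tremor_amplitude: dict = field(default_factory=lambda: {1: 0.0, 2: 1.5, 3: 3.0})
    spatial_scale: dict = field(default_factory=lambda: {1: 1.0, 2: 0.8, 3: 0.5})
    pupil_shift: dict = field(default_factory=lambda: {1: 0.0, 2: 0.1, 3: 0.2})
    pupil_sd_factor: dict = field(default_factory=lambda: {1: 1.0, 2: 0.7, 3: 0.4})
    allograph_fraction: float = 0.0

    def __post_init__(self) -> None:
        nyquist = self.sample_rate / 2.0
        if not (0 < self.omt_freq < nyquist) or not (0 < self.tremor_freq < nyquist):
            raise ValueError("oscillation frequencies must lie below Nyquist")
        for name in ("pursuit_noise_sd", "omt_amplitude", "pupil_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LabeledTrajectory:
    """A raw trajectory with its supervision labels."""

    trajectory: RawTrajectory
    label: str
    level: int = 1
    writer: str = "sim"
    alphabet: int = 0
    allograph: bool = False  # drawn from the symbol's alternate template


def curated_templates() -> dict[str, LetterTemplate]:
    """Ten stylized cursive strokes (loops, zigzags, arcs) in a 100x100 px box.

    Symbol identity is arbitrary for testing; shapes are chosen to be
    geometrically distinguishable, like letters of a small alphabet.
    """
    shapes = {
        # ascending loop, like a cursive "l"
        "loop": [(20, 10), (45, 40), (55, 90), (35, 95), (30, 60), (50, 20), (80, 10)],
        # three-peak zigzag, like a "w"
        "zigzag": [(5, 80), (20, 15), (35, 75), (50, 15), (65, 75), (80, 15), (95, 80)],
        # open arc, like a "c"
        "arc": [(80, 80), (45, 95), (15, 65), (15, 35), (45, 5), (80, 20)],
        # closed round stroke, like an "o"
        "circle": [(90, 50), (70, 90), (30, 90), (10, 50), (30, 10), (70, 10), (88, 45)],
        # double bend, like an "s"
        "ess": [(80, 90), (40, 95), (25, 70), (60, 55), (75, 30), (40, 5), (10, 15)],
        # descender with hook, like a "j"
        "hook": [(55, 95), (50, 60), (45, 25), (35, 5), (15, 10), (10, 30)],
        # two arches, like an "n"
        "arches": [(10, 10), (15, 70), (30, 85), (45, 15), (55, 75), (75, 85), (90, 10)],
        # sharp valley, like a "v"
        "vee": [(10, 90), (30, 50), (50, 10), (70, 50), (90, 90)],
        # inward spiral
        "spiral": [(10, 50), (45, 90), (85, 55), (55, 15), (30, 40), (55, 60), (60, 45)],
        # tall stem with shoulder, like an "h"
        "cane": [(20, 95), (25, 55), (28, 10), (35, 50), (60, 65), (75, 40), (85, 10)],
    }
    return {name: LetterTemplate(name, np.array(pts)) for name, pts in shapes.items()}


def _symbol_salt(symbol: str) -> int:
    return zlib.crc32(symbol.encode("utf-8"))


def procedural_template(
    symbol: str,
    seed: int = 0,
    box: float = 100.0,
    n_points: int = 7,
    variant: int = 0,
) -> LetterTemplate:
    """A seeded random smooth stroke, reproducible per (symbol, seed, variant).

    Control points follow a momentum random walk confined to the bounding
    box, giving curvy single strokes reminiscent of cursive writing.
    ``variant`` selects an alternative shape for the same symbol (an
    allograph).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([seed % 2**31, _symbol_salt(symbol), variant])
    )
    pts = [rng.uniform(0.2 * box, 0.8 * box, size=2)]
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(n_points - 1):
        heading += rng.normal(0, 1.2)
        step = rng.uniform(0.25 * box, 0.45 * box)
        nxt = pts[-1] + step * np.array([np.cos(heading), np.sin(heading)])
        nxt = np.clip(nxt, 2.0, box - 2.0)
        pts.append(nxt)
    return LetterTemplate(symbol, np.array(pts))


def template_set(symbols, seed: int = 0) -> dict[str, LetterTemplate]:
    """One template per symbol: curated shapes first, then procedural ones."""
    curated = list(curated_templates().values())
    out = {}
    for i, sym in enumerate(symbols):
        if i < len(curated):
            out[sym] = replace(curated[i], symbol=sym)
        else:
            out[sym] = procedural_template(sym, seed)
    return out


def generate_trajectory(
    template: LetterTemplate,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RawTrajectory:
    """Sample one noisy eye-written trace of a template.

    A cubic spline through the control points (at equally spaced times over
    the nominal duration) gives the clean pursuit path; pursuit noise, the
    high-frequency oscillation and the pupil series are added on top, and a
    short fixation-plus-saccade prefix is prepended with the configured
    probability.  Deterministic for a fixed seed.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(rng)
    fs = config.sample_rate
    m = template.points.shape[0]
    n = max(int(round(template.duration * fs)) + 1, m)  # endpoint inclusive
    t_ctrl = np.linspace(0.0, template.duration, m)
    spline = CubicSpline(t_ctrl, template.points, axis=0)
    tt = np.arange(n) / fs
    pos = spline(np.clip(tt, 0, template.duration))

    if config.pursuit_noise_sd > 0:
        pos = pos + rng.normal(0.0, config.pursuit_noise_sd, size=pos.shape)
    if config.omt_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=2)
        osc = config.omt_amplitude * np.sin(
            2 * np.pi * config.omt_freq * tt[:, None] + phases[None, :]
        )
        pos = pos + osc

    if rng.random() < config.saccade_prob:
        start = pos[0]
        angle = rng.uniform(0, 2 * np.pi)
        offset = start + config.saccade_amplitude * np.array([np.cos(angle), np.sin(angle)])
        n_fix, n_jump = 8, 3
        fix = offset + rng.normal(0.0, config.pursuit_noise_sd, size=(n_fix, 2))
        jump = np.linspace(offset, start, n_jump + 1)[:-1]
        pos = np.vstack([fix, jump, pos])

    n_total = pos.shape[0]
    t = np.arange(n_total) / fs
    pupil = config.pupil_baseline + rng.normal(0.0, config.pupil_noise_sd, size=n_total)
    return RawTrajectory(t=t, x=pos[:, 0], y=pos[:, 1], d=pupil)


def simulate_disability(
    traj: RawTrajectory,
    level: int,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RawTrajectory:
    """Apply the motor-impairment manipulation to a healthy trajectory.

    Level 1 is the identity.  Levels 2 and 3 shrink the trajectory about
    its centroid (factors 4/5 and 1/2), add a sinusoidal tremor on both
    axes (small then medium amplitude), shift the pupil mean up and scale
    the pupil deviations down.  Tremor phases are drawn from ``rng`` (or
    zero when no generator is given), so repeated exemplars differ.
    """
    config = config or GeneratorConfig()
    if level not in config.spatial_scale:
        raise ValueError(f"invalid disability level {level!r}")
    if level == 1:
        return traj
    rng = np.random.default_rng(rng) if rng is not None else None
    phases = rng.uniform(0, 2 * np.pi, size=2) if rng is not None else np.zeros(2)

    scale = config.spatial_scale[level]
    amp = config.tremor_amplitude[level]
    cx, cy = float(np.mean(traj.x)), float(np.mean(traj.y))
    x = cx + scale * (traj.x - cx)
    y = cy + scale * (traj.y - cy)
    if amp > 0:
        w = 2 * np.pi * config.tremor_freq * traj.t
        x = x + amp * np.sin(w + phases[0])
        y = y + amp * np.sin(w + phases[1])

    mean_d = float(np.mean(traj.d))
    d = mean_d + config.pupil_sd_factor[level] * (traj.d - mean_d) + config.pupil_shift[level]
    return RawTrajectory(t=traj.t, x=x, y=y, d=d)


def generate_database(
    symbols,
    n_alphabets: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    levels=(1,),
    templates: dict | None = None,
) -> list[LabeledTrajectory]:
    """A labeled exemplar database: ``n_alphabets`` exemplars per symbol.

    Each exemplar is seeded independently from ``(seed, alphabet, symbol,
    level)``, so the database is reproducible as a whole and any subset can
    be regenerated.  With a non-zero ``allograph_fraction``, that share of
    exemplars is drawn from an alternative (variant) template of the same
    symbol, mirroring allograph variability in real writing.
    """
    config = config or GeneratorConfig()
    symbols = list(symbols)
    templates = templates or template_set(symbols, seed)
    out: list[LabeledTrajectory] = []
    for alphabet in range(n_alphabets):
        for si, sym in enumerate(symbols):
            for level in levels:
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed % 2**31, alphabet, si, level])
                )
                tpl = templates[sym]
                allograph = (
                    config.allograph_fraction > 0
                    and rng.random() < config.allograph_fraction
                )
                if allograph:
                    tpl = procedural_template(sym, seed, variant=1)
                traj = generate_trajectory(tpl, config, rng)
                if level != 1:
                    traj = simulate_disability(traj, level, config, rng)
                out.append(
                    LabeledTrajectory(
                        traj, label=sym, level=level, alphabet=alphabet, allograph=allograph
                    )
                )
    return out
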