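"""Run configuration: every pipeline constant in one place.

Defaults are the reference operating point of the system: 75 Hz sampling,
binomial filter of order 20, acceleration trimming threshold 0.4 px/sample²
over the first 30 / last 5 samples, 2.6 Hz pursuit/tremor cutoff, at most
15 via-points with a 2 px minimum separation, Laplace pseudo-count 1e-7,
Gaussian table smoothing of order 15 / variance 2 for displacement terms
and order 7 / variance 1 for velocity terms, and a velocity discretization
scale of 30 (px/s per bin).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .model import ModelConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    sample_rate_hz: float = 75.0
    binomial_order: int = 20
    accel_threshold: float = 0.4
    trim_head: int = 30
    trim_tail: int = 5
    f0_hz: float = 2.6
    min_sep_px: float = 2.0
    max_via_points: int = 15
    alpha: float = 1e-7
    pos_kernel_order: int = 15
    pos_kernel_var: float = 2.0
    vel_kernel_order: int = 7
    vel_kernel_var: float = 1.0
    velocity_scale: float = 30.0
    position_scale: float = 2.5
    size_scale: float = 2.5
    a_scale: float = 100.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def model_config(self, symbols=None, levels=(1, 2, 3)) -> ModelConfig:
        """The model hyper-parameters implied by this run configuration."""
        kwargs = dict(
            levels=tuple(levels),
            n_via_points=self.max_via_points,
            alpha=self.alpha,
            pos_kernel_order=self.pos_kernel_order,
            pos_kernel_var=self.pos_kernel_var,
            vel_kernel_order=self.vel_kernel_order,
            vel_kernel_var=self.vel_kernel_var,
            velocity_scale=self.velocity_scale,
            position_scale=self.position_scale,
            size_scale=self.size_scale,
            a_scale=self.a_scale,
        )
        if symbols is not None:
            return ModelConfig.for_symbols(tuple(symbols), **kwargs)
        return ModelConfig(**kwargs)
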