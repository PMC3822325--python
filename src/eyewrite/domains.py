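"""Discrete variable domains of the joint probability model.

Every model variable lives on a finite ordered domain.  Via-point variables
carry one distinguished extra value, the termination WELL: an off-scale
marker that concentrates probability mass at via-point indices beyond a
trajectory's end, so that trajectory length never needs an explicit
variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WELL", "DomainSpec", "default_domains", "DEFAULT_SYMBOLS", "UNKNOWN_SYMBOL"]


class _Well:
    """Singleton sentinel for the termination marker."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "WELL"


WELL = _Well()

#: the novelty symbol: likelihood terms conditioned on it are uniform
UNKNOWN_SYMBOL = "$"

#: digits 1-9, letters a-z, and the unknown symbol — 36 values
DEFAULT_SYMBOLS: tuple[str, ...] = tuple(
    [str(i) for i in range(1, 10)] + [chr(c) for c in range(ord("a"), ord("z") + 1)]
) + (UNKNOWN_SYMBOL,)


@dataclass(frozen=True)
class DomainSpec:
    """An ordered finite domain, optionally extended with the WELL marker.

    ``values`` are the numeric (or fixed-step real) domain values in strictly
    increasing order; when ``has_well`` is true the WELL occupies one extra
    slot at the end of the probability axis, distinct from every numeric
    value.
    """

    name: str
    values: np.ndarray
    has_well: bool = False
    step: float = field(default=1.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.size < 1:
            raise ValueError("a domain needs at least one value")
        if np.any(np.diff(vals) <= 0):
            raise ValueError(f"domain {self.name!r}: values must be strictly increasing")

    @property
    def size(self) -> int:
        """Total number of probability slots, WELL included."""
        return int(self.values.size) + (1 if self.has_well else 0)

    @property
    def n_numeric(self) -> int:
        return int(self.values.size)

    @property
    def well_index(self) -> int:
        if not self.has_well:
            raise ValueError(f"domain {self.name!r} has no WELL value")
        return self.n_numeric

    def bin(self, value: float, scale: float = 1.0) -> int:
        """Map a continuous value to the index of the nearest domain value.

        The value is divided by ``scale``, snapped to the nearest grid point
        and clamped to the domain bounds; clamping absorbs out-of-range
        values silently (the caller may warn).
        """
        scaled = value / scale
        idx = int(round((scaled - self.values[0]) / self.step))
        return int(np.clip(idx, 0, self.n_numeric - 1))

    def index(self, value) -> int:
        """Index of an exact domain value (or the WELL sentinel)."""
        if value is WELL:
            return self.well_index
        idx = int(round((float(value) - self.values[0]) / self.step))
        if not (0 <= idx < self.n_numeric) or self.values[idx] != float(value):
            raise KeyError(f"{value!r} not in domain {self.name!r}")
        return idx


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def default_domains() -> dict[str, DomainSpec]:
    """The reference domain set.

    Relative displacements: 81 integers −40..40 plus WELL (82 slots);
    velocities: 21 integers −10..10 plus WELL (22); trajectory width/height:
    0..50 (51); band energy: 0..30 (31); mean pupil diameter: −1..1 in steps
    of 0.01 (201); pupil-diameter SD: 0..5 in steps of 0.1 (51).
    """
    return {
        "delta": DomainSpec("delta", _grid(-40, 40, 1), has_well=True, step=1.0),
        "vel": DomainSpec("vel", _grid(-10, 10, 1), has_well=True, step=1.0),
        "S": DomainSpec("S", _grid(0, 50, 1), step=1.0),
        "A": DomainSpec("A", _grid(0, 30, 1), step=1.0),
        "mu_p": DomainSpec("mu_p", _grid(-1, 1, 0.01), step=0.01),
        "sigma_p": DomainSpec("sigma_p", _grid(0, 5, 0.1), step=0.1),
    }
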