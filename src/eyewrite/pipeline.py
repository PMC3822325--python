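"""Glue between the deterministic front end and the probabilistic model."""

from __future__ import annotations

from .config import RunConfig
from .model import Exemplar
from .preprocessing import preprocess
from .simulate import LabeledTrajectory
from .trajectory import RawTrajectory

__all__ = ["featurize", "featurize_database"]


def featurize(item: LabeledTrajectory | RawTrajectory, config: RunConfig | None = None):
    """Run the preprocessing pipeline on one (possibly labeled) trajectory.

    For a labeled trajectory an :class:`Exemplar` is returned; for a bare
    record, the ``(via_points, aux)`` pair.
    """
    config = config or RunConfig()
    raw = item.trajectory if isinstance(item, LabeledTrajectory) else item
    vps, aux = preprocess(
        raw,
        binomial_order=config.binomial_order,
        accel_threshold=config.accel_threshold,
        trim_head=config.trim_head,
        trim_tail=config.trim_tail,
        max_via_points=config.max_via_points,
        min_sep=config.min_sep_px,
        f0=config.f0_hz,
    )
    if isinstance(item, LabeledTrajectory):
        return Exemplar(
            via_points=tuple(vps),
            aux=aux,
            label=item.label,
            level=item.level,
            writer=item.writer,
            alphabet=item.alphabet,
        )
    return vps, aux


def featurize_database(database, config: RunConfig | None = None) -> list[Exemplar]:
    """Featurize a whole labeled-trajectory database."""
    config = config or RunConfig()
    return [featurize(item, config) for item in database]
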