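"""Bayesian inference over the learned model.

All tasks are conditionings of the same joint distribution: the symbol
posterior given a growing prefix of via-points (online recognition), the
final posterior once auxiliary variables are available, novelty detection
through the uniform background symbol "$", and the disability-level
posterior.  Products of many small probabilities are accumulated in log
space, with the marginalization over the hidden variable done by
log-sum-exp, so 15-via-point products cannot underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .domains import UNKNOWN_SYMBOL
from .model import (
    DIMS,
    Exemplar,
    ModelConfig,
    ModelParameters,
    WELL_VIAPOINT,
    _discretize_sequence,
    _index_sequence,
    discretize_aux,
    learn_model,
)
from .trajectory import AuxFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "Posterior",
    "ConfusionMatrix",
    "CrossValidationResult",
    "letter_posterior_incremental",
    "letter_posterior_final",
    "novelty_posterior",
    "is_novel",
    "disability_posterior",
    "average_disability_posterior",
    "posterior_sequence",
    "shannon_entropy",
    "classify",
    "cross_validate",
]


@dataclass(frozen=True)
class Posterior:
    """A normalized probability distribution over symbols or disability levels."""

    labels: tuple
    probs: np.ndarray
    n_via_points: int = 0
    aux_included: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must be normalized with non-negative entries")

    def __getitem__(self, label) -> float:
        return float(self.probs[self.labels.index(label)])

    @property
    def argmax(self):
        return self.labels[int(np.argmax(self.probs))]


def shannon_entropy(posterior) -> float:
    """Entropy −Σ p ln p in nats (0·ln 0 = 0); maximal for a uniform posterior."""
    p = posterior.probs if isinstance(posterior, Posterior) else np.asarray(posterior, float)
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("entropy requires a normalized distribution")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def classify(posterior: Posterior):
    """Most probable value; exact ties go to the earliest label in domain order."""
    p = posterior.probs
    winners = np.flatnonzero(p == p.max())
    if winners.size > 1:
        logger.warning(
            "posterior tie between %s; keeping the first in domain order",
            [posterior.labels[i] for i in winners],
        )
    return posterior.labels[int(winners[0])]


def _viapoint_log_scores(model: ModelParameters, dvps) -> np.ndarray:
    """Accumulated log of the via-point likelihood terms: shape (n_symbols, n_levels).

    For each (l, h): sum over the four dimensions of
    log P(C^1 | l, h) + sum_{i=2..k} log P(C^i | C^{i-1}, l, h).
    """
    cfg = model.config
    S = np.zeros((cfg.n_symbols, cfg.n_levels))
    if not dvps:
        return S
    for dim in DIMS:
        dom = cfg.dim_domain(dim)
        idx = _index_sequence(dvps, dim, dom)
        S += np.log(model.tables[f"first_{dim}"][idx[0]])
        for i in range(2, len(dvps) + 1):
            S += np.log(model.tables[f"trans_{dim}_{i}"][idx[i - 1], idx[i - 2]])
    return S


def _normalize_log(log_p: np.ndarray) -> np.ndarray:
    log_p = log_p - logsumexp(log_p)
    p = np.exp(log_p)
    return p / p.sum()


def letter_posterior_incremental(model: ModelParameters, via_points, k: int | None = None) -> Posterior:
    """Posterior over symbols after the first ``k`` via-points.

    The symbol and level priors are uniform and cancel in the
    normalization; the hidden disability level is marginalized by
    log-sum-exp.  ``k = 0`` (no evidence) returns the uniform prior.
    Dropping the terms for via-points beyond ``k`` is exact marginalization,
    since each transition term sums to one over its target.
    """
    cfg = model.config
    dvps = _discretize_sequence(via_points, cfg)[: len(via_points) if k is None else k]
    if not dvps:
        return Posterior(cfg.symbols, np.full(cfg.n_symbols, 1.0 / cfg.n_symbols), 0)
    S = _viapoint_log_scores(model, dvps)
    return Posterior(cfg.symbols, _normalize_log(logsumexp(S, axis=1)), len(dvps))


def letter_posterior_final(model: ModelParameters, via_points, aux: AuxFeatures) -> Posterior:
    """Posterior over symbols for a completed trajectory.

    The via-point sequence is WELL-padded to the model length, and the
    size/band-energy likelihoods enter the level sum.  The pupil terms are
    independent of symbol identity and cancel.
    """
    cfg = model.config
    dvps = _discretize_sequence(via_points, cfg)
    S = _viapoint_log_scores(model, dvps)
    bins = discretize_aux(aux, cfg)
    for name in ("Sx", "Sy", "A"):
        S += np.log(model.tables[name][bins[name]])
    return Posterior(
        cfg.symbols, _normalize_log(logsumexp(S, axis=1)), len(dvps), aux_included=True
    )


def novelty_posterior(model: ModelParameters, via_points, k: int | None = None) -> Posterior:
    """Symbol posterior used for novelty detection.

    Identical to the incremental computation, with "$" participating
    through its uniform terms; the novelty decision is taken on this
    posterior, *before* auxiliary variables, because letter sizes vary too
    little across an alphabet to discriminate new symbols.
    """
    return letter_posterior_incremental(model, via_points, k)


def is_novel(posterior: Posterior, min_prob: float | None = None) -> bool:
    """Whether the trajectory should be proposed as a new symbol.

    Argmax rule by default; ``min_prob`` optionally additionally requires
    P("$") to exceed a threshold.
    """
    if posterior.argmax != UNKNOWN_SYMBOL:
        return False
    return min_prob is None or posterior[UNKNOWN_SYMBOL] >= min_prob


def disability_posterior(model: ModelParameters, via_points, aux: AuxFeatures) -> Posterior:
    """Posterior over disability levels for a completed trajectory.

    Marginalizes the symbol identity and includes every auxiliary term —
    the pupil terms no longer cancel, since they depend on the level.
    """
    cfg = model.config
    dvps = _discretize_sequence(via_points, cfg)
    S = _viapoint_log_scores(model, dvps)
    bins = discretize_aux(aux, cfg)
    for name in ("Sx", "Sy", "A"):
        S += np.log(model.tables[name][bins[name]])
    log_h = logsumexp(S, axis=0)
    log_h = log_h + np.log(model.tables["mu_p"][bins["mu_p"]])
    log_h = log_h + np.log(model.tables["sigma_p"][bins["sigma_p"]])
    return Posterior(cfg.levels, _normalize_log(log_h), len(dvps), aux_included=True)


def average_disability_posterior(model: ModelParameters, trials) -> Posterior:
    """Mean disability posterior over a sequence of (via_points, aux) trials.

    The averaged distribution is what would be recorded for later
    inspection by medical staff — a measurement, not a diagnosis.
    """
    posts = [disability_posterior(model, vps, aux).probs for vps, aux in trials]
    mean = np.mean(posts, axis=0)
    return Posterior(model.config.levels, mean / mean.sum(), aux_included=True)


def posterior_sequence(model: ModelParameters, via_points, aux: AuxFeatures | None = None):
    """Posteriors after each via-point of a completed trajectory.

    Returns the list ``[P(L), P(L|C^1), ..., P(L|C^1:n)]`` (the recorded
    trajectory is WELL-padded to the model length, so termination itself is
    evidence), plus the final posterior with auxiliary variables when
    ``aux`` is given.  Scores are accumulated once across prefixes.
    """
    cfg = model.config
    dvps = _discretize_sequence(via_points, cfg)
    out = [Posterior(cfg.symbols, np.full(cfg.n_symbols, 1.0 / cfg.n_symbols), 0)]
    S = np.zeros((cfg.n_symbols, cfg.n_levels))
    idx = {dim: _index_sequence(dvps, dim, cfg.dim_domain(dim)) for dim in DIMS}
    for i in range(1, len(dvps) + 1):
        for dim in DIMS:
            if i == 1:
                S += np.log(model.tables[f"first_{dim}"][idx[dim][0]])
            else:
                S += np.log(model.tables[f"trans_{dim}_{i}"][idx[dim][i - 1], idx[dim][i - 2]])
        out.append(Posterior(cfg.symbols, _normalize_log(logsumexp(S, axis=1)), i))
    if aux is not None:
        bins = discretize_aux(aux, cfg)
        for name in ("Sx", "Sy", "A"):
            S += np.log(model.tables[name][bins[name]])
        out.append(
            Posterior(cfg.symbols, _normalize_log(logsumexp(S, axis=1)), len(dvps), True)
        )
    return out


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of (presented, recognized) label pairs.

    Rows are presented labels; columns are recognizable labels and may
    include "$" (so the matrix need not be square).
    """

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    @property
    def rate(self) -> float:
        """Fraction of presentations recognized as their own label."""
        correct = sum(
            self.counts[i, self.col_labels.index(lab)]
            for i, lab in enumerate(self.row_labels)
            if lab in self.col_labels
        )
        return float(correct) / self.n_trials

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass(frozen=True)
class CrossValidationResult:
    confusion: ConfusionMatrix
    entropy_curve: np.ndarray  # mean entropy at k = 0..n_vp, then final-with-aux
    n_trials: int

    @property
    def rate(self) -> float:
        return self.confusion.rate


def cross_validate(exemplars, config: ModelConfig | None = None) -> CrossValidationResult:
    """Leave-one-alphabet-out recognition over a labeled exemplar database.

    For each fold, the model is learned on all other alphabets and every
    held-out character is classified from its final posterior (with
    auxiliary variables).  The mean entropy of the symbol posterior after
    each via-point is recorded alongside the confusion matrix.
    """
    exemplars = list(exemplars)
    groups: dict[int, list[Exemplar]] = {}
    for ex in exemplars:
        groups.setdefault(ex.alphabet, []).append(ex)
    if len(groups) < 2:
        raise ValueError("cross-validation needs at least 2 alphabet groups")

    labels = sorted({ex.label for ex in exemplars})
    if config is None:
        config = ModelConfig.for_symbols(labels)
    row_labels = tuple(labels)
    col_labels = config.symbols
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    entropy_sums = np.zeros(config.n_via_points + 2)
    n_trials = 0

    for fold in sorted(groups):
        test = groups[fold]
        train = [ex for a, g in groups.items() if a != fold for ex in g]
        if not test or not train:
            logger.warning("fold %r skipped: empty train or test group", fold)
            continue
        model = learn_model(train, config)
        for ex in test:
            posts = posterior_sequence(model, ex.via_points, ex.aux)
            recognized = classify(posts[-1])
            counts[row_labels.index(ex.label), col_labels.index(recognized)] += 1
            entropy_sums += [shannon_entropy(p) for p in posts]
            n_trials += 1

    cm = ConfusionMatrix(row_labels, col_labels, counts)
    return CrossValidationResult(cm, entropy_sums / max(n_trials, 1), n_trials)
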