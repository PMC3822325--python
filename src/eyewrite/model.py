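"""Discrete joint probability model over via-point sequences and features.

The model factorizes the joint distribution over the 15 four-dimensional
via-points, the auxiliary features, the symbol identity L and the
disability level H into a product of low-dimensional conditional tables:

    P(C, Sx, Sy, A, mu_p, sigma_p, L, H) =
        P(L) P(H)
        * prod_dims [ P(C^1_dim | L, H) * prod_{i=2..15} P(C^i_dim | C^{i-1}_dim, L, H) ]
        * P(Sx | L, H) P(Sy | L, H) P(A | L, H)
        * P(mu_p | H) P(sigma_p | H)

Via-point terms are Laplace succession laws (additive smoothing with a tiny
pseudo-count alpha) further smeared by a discrete Gaussian kernel to
compensate for a small exemplar database; auxiliary terms are truncated
discrete normal distributions.  Via-point indices beyond a trajectory's end
are absorbed by the termination WELL value; every term conditioned on the
unknown symbol "$" is uniform, which makes "$" a length-agnostic background
model for novelty detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .domains import DEFAULT_SYMBOLS, UNKNOWN_SYMBOL, WELL, DomainSpec, default_domains
from .trajectory import AuxFeatures, ViaPoint

logger = logging.getLogger(__name__)

__all__ = [
    "DIMS",
    "DiscreteViaPoint",
    "WELL_VIAPOINT",
    "Exemplar",
    "ModelConfig",
    "ConditionalTable",
    "ModelParameters",
    "discretize_viapoint",
    "discretize_aux",
    "laplace_probability",
    "gaussian_kernel",
    "smooth_table",
    "fit_truncated_discrete_normal",
    "learn_model",
    "count_parameters",
]

#: the four via-point dimensions, in canonical order
DIMS = ("dx", "dy", "vx", "vy")


@dataclass(frozen=True)
class DiscreteViaPoint:
    """A via-point after binning: integer bins or the termination WELL.

    Either all four fields are WELL (a padding marker beyond trajectory
    termination) or none is.
    """

    dx: object
    dy: object
    vx: object
    vy: object

    def __post_init__(self) -> None:
        wells = [getattr(self, f) is WELL for f in DIMS]
        if any(wells) and not all(wells):
            raise ValueError("WELL applies to all four via-point dimensions or none")

    @property
    def is_well(self) -> bool:
        return self.dx is WELL


WELL_VIAPOINT = DiscreteViaPoint(WELL, WELL, WELL, WELL)


@dataclass(frozen=True)
class Exemplar:
    """A featurized, labeled trajectory: the unit of supervised learning."""

    via_points: tuple
    aux: AuxFeatures
    label: str
    level: int = 1
    writer: str = ""
    alphabet: int = 0


@dataclass(frozen=True)
class ModelConfig:
    """Domains, symbol set and learning hyper-parameters of one model.

    ``alpha`` is the Laplace pseudo-count controlling how quickly observed
    frequencies overwhelm the uniform prior (very small by default, so one
    observation already dominates).  The Gaussian smoothing kernels smear
    learned probability peaks over neighboring bins, emulating a larger
    database with shape variability.  The three scale factors map raw
    measurements onto the discrete domains: velocities in px/s are divided
    by ``velocity_scale``, displacements and sizes in px by
    ``position_scale``/``size_scale``, band energy in (px/s)^2 by
    ``a_scale``.
    """

    symbols: tuple = DEFAULT_SYMBOLS
    levels: tuple = (1, 2, 3)
    n_via_points: int = 15
    domains: dict = field(default_factory=default_domains)
    alpha: float = 1e-7
    pos_kernel_order: int = 15
    pos_kernel_var: float = 2.0
    vel_kernel_order: int = 7
    vel_kernel_var: float = 1.0
    velocity_scale: float = 30.0
    position_scale: float = 2.5
    size_scale: float = 2.5
    a_scale: float = 100.0

    def __post_init__(self) -> None:
        if UNKNOWN_SYMBOL not in self.symbols:
            object.__setattr__(self, "symbols", tuple(self.symbols) + (UNKNOWN_SYMBOL,))
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate symbols")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @classmethod
    def for_symbols(cls, symbols, **kwargs) -> "ModelConfig":
        """A default-domain config whose symbol set is ``symbols`` + \"$\"."""
        return cls(symbols=tuple(symbols), **kwargs)

    @property
    def n_symbols(self) -> int:
        return len(self.symbols)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def symbol_index(self, label: str) -> int:
        return self.symbols.index(label)

    def level_index(self, level: int) -> int:
        return self.levels.index(level)

    def dim_domain(self, dim: str) -> DomainSpec:
        return self.domains["delta" if dim in ("dx", "dy") else "vel"]


def discretize_viapoint(
    vp: ViaPoint,
    velocity_scale: float = 30.0,
    position_scale: float = 2.5,
    domains: dict | None = None,
) -> DiscreteViaPoint:
    """Bin a continuous via-point onto the discrete model domains.

    Velocities are divided by ``velocity_scale`` and rounded to the nearest
    integer bin in −10..10; displacements are divided by ``position_scale``
    and rounded into −40..40.  Clamping absorbs out-of-range values.
    """
    domains = domains or default_domains()
    dd, dv = domains["delta"], domains["vel"]
    return DiscreteViaPoint(
        dx=int(dd.values[dd.bin(vp.dx, position_scale)]),
        dy=int(dd.values[dd.bin(vp.dy, position_scale)]),
        vx=int(dv.values[dv.bin(vp.vx, velocity_scale)]),
        vy=int(dv.values[dv.bin(vp.vy, velocity_scale)]),
    )


def discretize_aux(aux: AuxFeatures, config: ModelConfig) -> dict:
    """Bin auxiliary features; off-domain values are clamped with a warning."""
    dom = config.domains
    raw = {
        "Sx": (aux.sx / config.size_scale, dom["S"]),
        "Sy": (aux.sy / config.size_scale, dom["S"]),
        "A": (aux.a / config.a_scale, dom["A"]),
        "mu_p": (aux.mu_p, dom["mu_p"]),
        "sigma_p": (aux.sigma_p, dom["sigma_p"]),
    }
    out = {}
    for name, (value, d) in raw.items():
        if not (d.values[0] - d.step / 2 <= value <= d.values[-1] + d.step / 2):
            logger.warning("aux feature %s=%.3g outside domain; clamped", name, value)
        out[name] = d.bin(value)
    return out


def laplace_probability(n_i, N: float, K: int, alpha: float):
    """Laplace succession law ``(n_i + alpha) / (N + alpha*K)``.

    Strictly positive for every value; tends to the empirical frequency for
    alpha → 0 with data, and to the uniform 1/K with no data.
    """
    n_i = np.asarray(n_i, dtype=float)
    if K < 1:
        raise ValueError("domain size K must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(n_i < 0) or np.any(n_i > N):
        raise ValueError("counts must satisfy 0 <= n_i <= N")
    out = (n_i + alpha) / (N + alpha * K)
    return float(out) if out.ndim == 0 else out


def gaussian_kernel(order: int, variance: float) -> np.ndarray:
    """Truncated discrete Gaussian kernel of support length ``order`` (odd)."""
    if order < 1 or order % 2 == 0:
        raise ValueError("kernel order must be a positive odd integer")
    if variance <= 0:
        raise ValueError("kernel variance must be positive")
    offsets = np.arange(order) - (order - 1) / 2
    k = np.exp(-(offsets**2) / (2.0 * variance))
    return k / k.sum()


def _smooth_slice(p: np.ndarray, kernel: np.ndarray, well_index: int | None) -> np.ndarray:
    """Smooth one probability slice along its numeric axis.

    The WELL entry, when present, is excluded from the smearing: its mass is
    held fixed and the numeric part is renormalized to the remaining mass.
    """
    if well_index is None:
        numeric, well_mass = p, None
    else:
        numeric, well_mass = p[:well_index], p[well_index]
    sm = ndimage.convolve1d(numeric, kernel, mode="reflect")
    target = 1.0 if well_mass is None else 1.0 - well_mass
    total = sm.sum()
    if total > 0:
        sm = sm * (target / total)
    if well_mass is None:
        return sm
    return np.concatenate([sm, [well_mass]])


@dataclass(frozen=True)
class ConditionalTable:
    """A conditional probability table with the target variable on axis 0.

    Every conditional slice (a column, once the conditioning axes are
    flattened) sums to one.
    """

    name: str
    target: DomainSpec
    array: np.ndarray
    cond_names: tuple = ()

    def __post_init__(self) -> None:
        if self.array.shape[0] != self.target.size:
            raise ValueError("axis 0 must match the target domain size")
        sums = self.array.reshape(self.array.shape[0], -1).sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"table {self.name!r}: conditional slices must sum to 1")


def smooth_table(table: ConditionalTable, kernel_order: int, kernel_variance: float) -> ConditionalTable:
    """Gaussian-smooth every conditional slice of a table along its target axis."""
    if kernel_order > table.target.n_numeric:
        raise ValueError("smoothing kernel longer than the numeric domain")
    kernel = gaussian_kernel(kernel_order, kernel_variance)
    well = table.target.well_index if table.target.has_well else None
    flat = table.array.reshape(table.array.shape[0], -1)
    out = np.empty_like(flat)
    for j in range(flat.shape[1]):
        out[:, j] = _smooth_slice(flat[:, j], kernel, well)
    return replace(table, array=out.reshape(table.array.shape))


def fit_truncated_discrete_normal(
    samples, domain: DomainSpec, sd_floor: float | None = None
) -> np.ndarray:
    """Fit a normal to samples and discretize it onto a finite domain.

    The density is evaluated at every domain value, set to zero outside the
    domain (truncation — negative sizes or energies get no mass) and
    renormalized.  A single sample (or identical samples) would give a
    degenerate density, so the SD is floored at half a domain step by
    default.  Evaluation is done in log space so off-domain means degrade
    gracefully into a monotone tail instead of underflowing to 0/0, and a
    tiny uniform floor (1e-12 before renormalization) keeps every domain
    value representable, so log-space inference never sees a hard zero for
    a merely improbable observation.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    if sd_floor is None:
        sd_floor = domain.step / 2.0
    mean = float(np.mean(samples))
    sd = max(float(np.std(samples)), sd_floor)
    logpdf = norm.logpdf(domain.values, loc=mean, scale=sd)
    logpdf -= logpdf.max()
    pdf = np.exp(logpdf) + 1e-12
    return pdf / pdf.sum()


@dataclass
class ModelParameters:
    """The complete learned term set of the joint decomposition.

    ``counts`` holds raw occurrence counts (so adding a confirmed trajectory
    to the database later is exact), ``tables`` the normalized (and
    smoothed) probability tables.  Table keys::

        first_<dim>          shape (D, n_symbols, n_levels)
        trans_<dim>_<i>      shape (D, D, n_symbols, n_levels), i = 2..n_via_points
                             indexed [current, previous, symbol, level]
        Sx, Sy, A            shape (D_aux, n_symbols, n_levels)
        mu_p, sigma_p        shape (D_pupil, n_levels)
        L, H                 uniform priors
    """

    config: ModelConfig
    counts: dict
    tables: dict
    aux_stats: dict
    exemplar_counts: np.ndarray  # (n_symbols, n_levels)

    def validate(self) -> None:
        """Check that every conditional slice sums to 1 and is positive."""
        for key, arr in self.tables.items():
            sums = arr.reshape(arr.shape[0], -1).sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"term {key!r} has unnormalized slices")
            if key.startswith(("first_", "trans_")) and not np.all(arr > 0):
                raise ValueError(f"Laplace term {key!r} has non-positive entries")


def _discretize_sequence(via_points, config: ModelConfig) -> list[DiscreteViaPoint]:
    """Discretize and WELL-pad a via-point sequence to the model length."""
    dvps = [
        vp
        if isinstance(vp, DiscreteViaPoint)
        else discretize_viapoint(vp, config.velocity_scale, config.position_scale, config.domains)
        for vp in via_points[: config.n_via_points]
    ]
    dvps += [WELL_VIAPOINT] * (config.n_via_points - len(dvps))
    return dvps


def _index_sequence(dvps, dim: str, domain: DomainSpec) -> np.ndarray:
    return np.array([domain.index(getattr(vp, dim)) for vp in dvps], dtype=np.intp)


def learn_model(exemplars, config: ModelConfig | None = None) -> ModelParameters:
    """Supervised parameter identification from a labeled exemplar database.

    Occurrence counting over WELL-padded discretized via-point sequences,
    Laplace succession laws, Gaussian smoothing of observed slices, and
    truncated discrete normal fits for the auxiliary terms.  Terms
    conditioned on the unknown symbol "$" are uniform; the symbol and level
    priors are uniform.  Cells (L, H) without exemplars keep the Laplace
    uniform prior (logged as a warning, not an error).  Without an explicit
    config, the symbol and level sets are inferred from the exemplar labels
    (plus "$") over the default domains.
    """
    exemplars = list(exemplars)
    if config is None:
        config = ModelConfig.for_symbols(
            tuple(sorted({ex.label for ex in exemplars})),
            levels=tuple(sorted({ex.level for ex in exemplars})),
        )
    nL, nH, n_vp = config.n_symbols, config.n_levels, config.n_via_points
    dollar = config.symbol_index(UNKNOWN_SYMBOL)

    counts: dict[str, np.ndarray] = {}
    for dim in DIMS:
        D = config.dim_domain(dim).size
        counts[f"first_{dim}"] = np.zeros((D, nL, nH), dtype=np.int64)
        for i in range(2, n_vp + 1):
            counts[f"trans_{dim}_{i}"] = np.zeros((D, D, nL, nH), dtype=np.int64)

    exemplar_counts = np.zeros((nL, nH), dtype=np.int64)
    aux_samples: dict[str, dict] = {k: {} for k in ("Sx", "Sy", "A")}
    pupil_samples: dict[str, dict] = {k: {} for k in ("mu_p", "sigma_p")}

    for ex in exemplars:
        if ex.label == UNKNOWN_SYMBOL:
            raise ValueError('the unknown symbol "$" cannot be a training label')
        l = config.symbol_index(ex.label)
        h = config.level_index(ex.level)
        exemplar_counts[l, h] += 1
        dvps = _discretize_sequence(ex.via_points, config)
        for dim in DIMS:
            dom = config.dim_domain(dim)
            idx = _index_sequence(dvps, dim, dom)
            counts[f"first_{dim}"][idx[0], l, h] += 1
            for i in range(2, n_vp + 1):
                counts[f"trans_{dim}_{i}"][idx[i - 1], idx[i - 2], l, h] += 1
        aux_samples["Sx"].setdefault((l, h), []).append(ex.aux.sx / config.size_scale)
        aux_samples["Sy"].setdefault((l, h), []).append(ex.aux.sy / config.size_scale)
        aux_samples["A"].setdefault((l, h), []).append(ex.aux.a / config.a_scale)
        pupil_samples["mu_p"].setdefault(h, []).append(ex.aux.mu_p)
        pupil_samples["sigma_p"].setdefault(h, []).append(ex.aux.sigma_p)

    empty = [
        (config.symbols[l], config.levels[h])
        for l in range(nL)
        for h in range(nH)
        if l != dollar and exemplar_counts[l, h] == 0
    ]
    if empty:
        logger.warning(
            "%d (symbol, level) cells have no exemplars and keep the uniform prior",
            len(empty),
        )

    tables: dict[str, np.ndarray] = {}
    for dim in DIMS:
        dom = config.dim_domain(dim)
        is_pos = dim in ("dx", "dy")
        order = config.pos_kernel_order if is_pos else config.vel_kernel_order
        var = config.pos_kernel_var if is_pos else config.vel_kernel_var
        kernel = gaussian_kernel(order, var)
        for key in [f"first_{dim}"] + [f"trans_{dim}_{i}" for i in range(2, n_vp + 1)]:
            tables[key] = _build_viapoint_table(
                counts[key], dom, config.alpha, kernel, dollar
            )

    sd = config.domains["S"]
    ad = config.domains["A"]
    for name, dom in (("Sx", sd), ("Sy", sd), ("A", ad)):
        arr = np.full((dom.size, nL, nH), 1.0 / dom.size)
        for (l, h), vals in aux_samples[name].items():
            arr[:, l, h] = fit_truncated_discrete_normal(np.sort(vals), dom)
        arr[:, dollar, :] = 1.0 / dom.size
        tables[name] = arr
    for name in ("mu_p", "sigma_p"):
        dom = config.domains[name]
        arr = np.full((dom.size, nH), 1.0 / dom.size)
        for h, vals in pupil_samples[name].items():
            arr[:, h] = fit_truncated_discrete_normal(np.sort(vals), dom)
        tables[name] = arr

    tables["L"] = np.full(nL, 1.0 / nL)
    tables["H"] = np.full(nH, 1.0 / nH)

    aux_stats = _aux_sufficient_stats(aux_samples, pupil_samples, nL, nH)
    return ModelParameters(
        config=config,
        counts=counts,
        tables=tables,
        aux_stats=aux_stats,
        exemplar_counts=exemplar_counts,
    )


def _build_viapoint_table(
    cnt: np.ndarray, dom: DomainSpec, alpha: float, kernel: np.ndarray, dollar: int
) -> np.ndarray:
    """Laplace law over axis 0, Gaussian smoothing of observed slices, "$" uniform.

    Slices with no observations are exactly the uniform 1/K, which is a
    fixed point of the (reflect-boundary, WELL-preserving) smoothing, so
    only observed slices need the convolution.
    """
    K = dom.size
    flat_cnt = cnt.reshape(K, -1)
    N = flat_cnt.sum(axis=0)
    table = (flat_cnt + alpha) / (N + alpha * K)
    well = dom.well_index if dom.has_well else None
    for j in np.flatnonzero(N > 0):
        table[:, j] = _smooth_slice(table[:, j], kernel, well)
    table = table.reshape(cnt.shape)
    uniform = 1.0 / K
    if cnt.ndim == 3:  # first-via-point term: (D, L, H)
        table[:, dollar, :] = uniform
    else:  # transition term: (D, D, L, H)
        table[:, :, dollar, :] = uniform
    return table


def _aux_sufficient_stats(aux_samples, pupil_samples, nL, nH) -> dict:
    """Per-cell (n, sum, sum of squares) for exact incremental refits."""
    stats = {}
    for name, cells in aux_samples.items():
        n = np.zeros((nL, nH))
        s = np.zeros((nL, nH))
        ss = np.zeros((nL, nH))
        for (l, h), vals in cells.items():
            v = np.sort(vals)
            n[l, h], s[l, h], ss[l, h] = len(v), v.sum(), (v**2).sum()
        stats[name] = np.stack([n, s, ss])
    for name, cells in pupil_samples.items():
        n = np.zeros(nH)
        s = np.zeros(nH)
        ss = np.zeros(nH)
        for h, vals in cells.items():
            v = np.sort(vals)
            n[h], s[h], ss[h] = len(v), v.sum(), (v**2).sum()
        stats[name] = np.stack([n, s, ss])
    return stats


def count_parameters(config: ModelConfig | None = None) -> tuple[dict, int]:
    """Raw table-entry counts per term of the decomposition, and their sum.

    With the reference domains, one displacement transition term
    P(C^i | C^{i-1}, L, H) has 82 * 82 * 36 * 3 = 726,192 entries.
    """
    config = config or ModelConfig()
    nL, nH, n_vp = config.n_symbols, config.n_levels, config.n_via_points
    per_term: dict[str, int] = {}
    for dim in DIMS:
        D = config.dim_domain(dim).size
        per_term[f"first_{dim}"] = D * nL * nH
        for i in range(2, n_vp + 1):
            per_term[f"trans_{dim}_{i}"] = D * D * nL * nH
    sd, ad = config.domains["S"], config.domains["A"]
    per_term["Sx"] = sd.size * nL * nH
    per_term["Sy"] = sd.size * nL * nH
    per_term["A"] = ad.size * nL * nH
    per_term["mu_p"] = config.domains["mu_p"].size * nH
    per_term["sigma_p"] = config.domains["sigma_p"].size * nH
    per_term["L"] = nL
    per_term["H"] = nH
    return per_term, int(sum(per_term.values()))
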