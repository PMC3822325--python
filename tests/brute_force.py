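"""Independent brute-force inference oracle for miniature models.

Computes posteriors by explicit enumeration: plain Python loops over every
domain value, linear-space products of table entries, and explicit sums for
every unobserved variable (no log-space tricks, no vectorized indexing).
Only feasible for tiny domains and short via-point sequences; used to check
the package's log-space inference against conditioning of the fully
enumerated joint distribution.
"""

from itertools import product

import numpy as np

from eyewrite.model import DIMS


def _chain_likelihood(model, dim, obs_idx, l, h):
    """P(observed prefix | l, h) for one via-point dimension.

    Unobserved suffix via-points are marginalized by explicit enumeration
    over all domain values.
    """
    cfg = model.config
    dom = cfg.dim_domain(dim)
    n_vp = cfg.n_via_points
    k = len(obs_idx)
    first = model.tables[f"first_{dim}"]
    prefix = first[obs_idx[0], l, h] if k else 1.0
    for i in range(2, k + 1):
        prefix *= model.tables[f"trans_{dim}_{i}"][obs_idx[i - 1], obs_idx[i - 2], l, h]
    if k == n_vp or k == 0:
        return prefix
    total = 0.0
    for suffix in product(range(dom.size), repeat=n_vp - k):
        p = 1.0
        prev = obs_idx[-1]
        for step, v in enumerate(suffix):
            p *= model.tables[f"trans_{dim}_{k + 1 + step}"][v, prev, l, h]
            prev = v
        total += p
    return prefix * total


def _aux_likelihood(model, name, obs_bin, l, h):
    """P(aux | l, h): the observed entry, or an explicit sum to 1 if unobserved."""
    table = model.tables[name]
    if obs_bin is not None:
        return table[obs_bin, l, h]
    return sum(table[v, l, h] for v in range(table.shape[0]))


def _pupil_likelihood(model, name, obs_bin, h):
    table = model.tables[name]
    if obs_bin is not None:
        return table[obs_bin, h]
    return sum(table[v, h] for v in range(table.shape[0]))


def _joint_terms(model, l, h, obs, aux_bins, pupil_bins):
    p = model.tables["L"][l] * model.tables["H"][h]
    for dim in DIMS:
        p *= _chain_likelihood(model, dim, obs[dim], l, h)
    for name in ("Sx", "Sy", "A"):
        p *= _aux_likelihood(model, name, aux_bins.get(name), l, h)
    for name in ("mu_p", "sigma_p"):
        p *= _pupil_likelihood(model, name, pupil_bins.get(name), h)
    return p


def _observed_indices(model, dvps):
    cfg = model.config
    return {
        dim: [cfg.dim_domain(dim).index(getattr(vp, dim)) for vp in dvps] for dim in DIMS
    }


def oracle_letter_posterior(model, dvps, aux_bins=None):
    """P(L | via-points [, Sx, Sy, A]) by explicit joint enumeration.

    Pupil variables are always unobserved here (they carry no information
    about symbol identity).
    """
    cfg = model.config
    obs = _observed_indices(model, dvps)
    aux_bins = aux_bins or {}
    weights = np.array(
        [
            sum(
                _joint_terms(model, l, h, obs, aux_bins, {})
                for h in range(cfg.n_levels)
            )
            for l in range(cfg.n_symbols)
        ]
    )
    return weights / weights.sum()


def oracle_disability_posterior(model, dvps, aux_bins, pupil_bins):
    """P(H | via-points, all auxiliary variables) by explicit enumeration."""
    cfg = model.config
    obs = _observed_indices(model, dvps)
    weights = np.array(
        [
            sum(
                _joint_terms(model, l, h, obs, aux_bins, pupil_bins)
                for l in range(cfg.n_symbols)
            )
            for h in range(cfg.n_levels)
        ]
    )
    return weights / weights.sum()
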