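"""Shared fixtures: a miniature model for oracle checks and a synthetic database."""

import numpy as np
import pytest

from eyewrite import (
    AuxFeatures,
    GeneratorConfig,
    ModelConfig,
    ViaPoint,
    curated_templates,
    featurize_database,
    generate_database,
    learn_model,
)
from eyewrite.domains import DomainSpec
from eyewrite.model import Exemplar


def mini_domains():
    """Tiny domains: enumeration over the full joint stays feasible."""
    return {
        "delta": DomainSpec("delta", np.arange(-2, 3), has_well=True),
        "vel": DomainSpec("vel", np.arange(-1, 2), has_well=True),
        "S": DomainSpec("S", np.arange(0, 5)),
        "A": DomainSpec("A", np.arange(0, 3)),
        "mu_p": DomainSpec("mu_p", np.arange(-1, 2), step=1.0),
        "sigma_p": DomainSpec("sigma_p", np.arange(0, 3), step=1.0),
    }


@pytest.fixture(scope="session")
def mini_config():
    return ModelConfig(
        symbols=("u", "n", "$"),
        levels=(1, 2),
        n_via_points=4,
        domains=mini_domains(),
        pos_kernel_order=3,
        pos_kernel_var=0.5,
        vel_kernel_order=3,
        vel_kernel_var=0.5,
        velocity_scale=1.0,
        position_scale=1.0,
        size_scale=1.0,
        a_scale=1.0,
    )


def _vp(k, dx, dy, vx, vy):
    return ViaPoint(dx=dx, dy=dy, vx=vx, vy=vy, index=k)


def mini_exemplars():
    """Handmade exemplars on the miniature domains: two shapes, two levels."""
    aux_u = AuxFeatures(sx=3.0, sy=2.0, a=1.0, mu_p=0.0, sigma_p=1.0)
    aux_n = AuxFeatures(sx=2.0, sy=3.0, a=0.0, mu_p=1.0, sigma_p=2.0)
    u1 = (_vp(1, 0, 0, 1, -1), _vp(2, 1, -2, 1, 0), _vp(3, 1, 2, 0, 1))
    u2 = (_vp(1, 0, 0, 1, -1), _vp(2, 2, -2, 1, 0), _vp(3, 1, 1, 0, 1), _vp(4, 0, 2, -1, 1))
    n1 = (_vp(1, 0, 0, -1, 1), _vp(2, -1, 2, 0, 1), _vp(3, -2, -1, -1, 0))
    n2 = (_vp(1, 0, 0, -1, 1), _vp(2, -2, 1, 0, 1))
    out = []
    for level in (1, 2):
        out.append(Exemplar(u1, aux_u, "u", level))
        out.append(Exemplar(u2, aux_u, "u", level))
        out.append(Exemplar(n1, aux_n, "n", level))
        out.append(Exemplar(n2, aux_n, "n", level))
    return out


@pytest.fixture(scope="session")
def mini_model(mini_config):
    return learn_model(mini_exemplars(), mini_config)


@pytest.fixture(scope="session")
def symbols10():
    return list(curated_templates())


@pytest.fixture(scope="session")
def db10(symbols10):
    """10 curated symbols x 9 alphabets at default generator settings, featurized."""
    raw = generate_database(symbols10, 9, GeneratorConfig(), seed=7)
    return featurize_database(raw)
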