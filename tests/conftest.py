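"""Shared fixtures: the default study conditions, built once per session.

The toy head at resolution 6, the default two-blob DMN template, its
gray-matter DMN element set, and the seed-0 scenario libraries (with the
default 5% multiplicative noise, and noise-free) are expensive enough to
share across test modules.
"""

import numpy as np
import pytest

import impactdmn as im


@pytest.fixture(scope="session")
def mesh():
    return im.build_toy_head_mesh(6, seed=0)


@pytest.fixture(scope="session")
def template():
    return im.default_dmn_template()


@pytest.fixture(scope="session")
def dmn_ids(mesh, template):
    return im.map_dmn_elements(mesh, template.binarize(), template.affine)


@pytest.fixture(scope="session")
def library(mesh, dmn_ids):
    """Default seed-0 library (noise_cv 0.05), fractured records removed."""
    params = im.SurrogateParams(seed=0)
    records = im.build_scenario_library(mesh, params, dmn_ids)
    return [r for r in records if not r.fractured]


@pytest.fixture(scope="session")
def clean_library(mesh, dmn_ids):
    """Noise-free library: damage is a deterministic threshold rule."""
    params = im.SurrogateParams(seed=0, noise_cv=0.0)
    records = im.build_scenario_library(mesh, params, dmn_ids)
    return [r for r in records if not r.fractured]


@pytest.fixture(scope="session")
def aux_template(template):
    """A second, non-DMN network template on the same grid."""
    return im.build_dmn_template((16, 16, 16), template.affine,
                                 [(0.0, 0.0, -0.05)], 0.03, 5.0, name="aux")


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
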