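"""Shared fixtures: small synthetic heads and meshed-sphere BEM operators.

Session-scoped where construction is expensive; all geometry is generated
programmatically (no fixture files).
"""

import numpy as np
import pytest

from atrophysim.bem_forward import BemOptions, assemble_bem
from atrophysim.geometry import (
    HeadModel,
    SourceSpace,
    SphericalModel,
    SyntheticHeadConfig,
    TriSurface,
    make_icosphere,
    make_synthetic_head,
)

SPHERE_RADII = (1.0, 0.90, 0.83, 0.78)
SPHERE_SIGMA = (0.3, 0.006, 1.5, 0.3)


@pytest.fixture(scope="session")
def sphere_model() -> SphericalModel:
    return SphericalModel()


@pytest.fixture(scope="session")
def sphere_mesh_head() -> HeadModel:
    """Concentric four-layer icosphere head at subdivision 2 (162 verts per
    surface), the desk-scale BEM test geometry."""
    ico = make_icosphere(2, 1.0)
    surfaces = [TriSurface(ico.vertices * r, ico.triangles.copy()) for r in SPHERE_RADII]
    return HeadModel(surfaces, SPHERE_SIGMA, units="relative")


@pytest.fixture(scope="session")
def sphere_mesh_operator(sphere_mesh_head):
    return assemble_bem(sphere_mesh_head, BemOptions(use_isa=True))


@pytest.fixture(scope="session")
def small_synthetic_head():
    """Perturbed synthetic head at subdivision 2, seeded."""
    cfg = SyntheticHeadConfig(seed=1, subdivision=2, source_subdivision=3)
    return make_synthetic_head(cfg)


@pytest.fixture
def axial_test_sources() -> SourceSpace:
    """Radial + tangential dipoles on the z-axis at a few eccentricities."""
    z = np.array([0.0, 0.0, 1.0])
    t = np.array([1.0, 0.0, 0.0])
    pos, ori = [], []
    for ecc in (0.3, 0.5):
        p = z * (ecc * SPHERE_RADII[-1])
        pos += [p, p]
        ori += [z, t]
    return SourceSpace(np.array(pos), np.array(ori))
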