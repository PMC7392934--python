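"""Shared synthetic fixtures (session-scoped: voxelization is the slow part)."""

import numpy as np
import pytest

from ossimetrics import synthetic as syn


@pytest.fixture(scope="session")
def sphere_phantom():
    """Voxelized solid sphere, r = 0.4 mm at 0.01 mm spacing, off-grid center."""
    spec = syn.PhantomSpec(
        primitives=(syn.Sphere(center=(0.003, 0.001, -0.002), radius=0.4),),
        spacing=0.01)
    return syn.voxelize(spec, density=1.0)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Voxelized solid ellipsoid, semi-axes (0.8, 0.4, 0.2) mm at 0.01 mm."""
    spec = syn.PhantomSpec(
        primitives=(syn.Ellipsoid(center=(0.0013, 0.0007, -0.0004),
                                  semi_axes=(0.8, 0.4, 0.2)),),
        spacing=0.01)
    return syn.voxelize(spec, density=1.0)


@pytest.fixture(scope="session")
def sheep_malleus():
    return syn.toy_ossicle("malleus", "sheep", seed=3)


@pytest.fixture(scope="session")
def sheep_incus():
    return syn.toy_ossicle("incus", "sheep", seed=4)


@pytest.fixture(scope="session")
def sheep_stapes():
    return syn.toy_ossicle("stapes", "sheep", seed=5)


@pytest.fixture(scope="session")
def sheep_chain():
    return syn.toy_ossicle("chain", "sheep", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_925)
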