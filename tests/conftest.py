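import numpy as np
import pytest

from vwiloc.core import VolumeGeometry
from vwiloc.phantom import CohortParams, make_cohort, make_template, render_pair
from vwiloc.tree import Branch, VesselTree

SMALL_GEOM = VolumeGeometry((24, 48, 40), (2.2, 2.2, 2.2))
SMALL_PARAMS = CohortParams(geometry=SMALL_GEOM, tree_margin=6.0)


@pytest.fixture(scope="session")
def template_case():
    """The working-grid template phantom (clean render)."""
    return make_template(7)


@pytest.fixture(scope="session")
def small_template():
    return make_template(7, SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_cohort():
    """Five noisy subjects on the reduced grid, shared across tests."""
    return make_cohort(5, 21, SMALL_PARAMS)


def straight_cylinder(radius: float, spacing: float = 1.0, noise_sd: float = 0.0,
                      seed: int = 1):
    """A straight tube along axis 1 and its rendered (VWI, MRA) pair."""
    geom = VolumeGeometry((40, 64, 40), (spacing,) * 3)
    n = 80
    pts = np.column_stack([np.full(n, 20.0), np.linspace(5, 58, n), np.full(n, 20.0)])
    tree = VesselTree([Branch(pts, np.full(n, radius), -1)])
    vwi, mra = render_pair(tree, geom, noise_sd=noise_sd, seed=seed, bias=False)
    return tree, vwi, mra


def y_tree_volume(noise_sd: float = 2.0, seed: int = 3):
    """A Y-shaped bifurcating tree and its rendered MRA."""
    geom = VolumeGeometry((48, 64, 48), (1.0, 1.0, 1.0))
    n = 60
    trunk = np.column_stack([np.full(n, 24.0), np.linspace(4, 30, n), np.full(n, 24.0)])
    arm_a = np.column_stack([24 + np.linspace(0, 14, n), 30 + np.linspace(0, 26, n),
                             np.full(n, 24.0)])
    arm_b = np.column_stack([24 - np.linspace(0, 14, n), 30 + np.linspace(0, 26, n),
                             np.full(n, 24.0)])
    tree = VesselTree([
        Branch(trunk, np.full(n, 2.0), -1),
        Branch(arm_a, np.linspace(1.8, 1.2, n), 0),
        Branch(arm_b, np.linspace(1.8, 1.2, n), 0),
    ])
    _, mra = render_pair(tree, geom, noise_sd=noise_sd, seed=seed, bias=False)
    return tree, mra


@pytest.fixture(scope="session")
def cylinder_r2():
    return straight_cylinder(2.0)


@pytest.fixture(scope="session")
def y_phantom():
    return y_tree_volume()
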