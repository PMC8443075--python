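import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from icrsfem.experiments import headline_cases
from icrsfem.geometry import CorneaGeometry
from icrsfem.materials import MaterialSpec
from icrsfem.mesh import annular_sector_mesh


@pytest.fixture(scope="session")
def cases():
    """All headline implantation runs (both modes), computed once."""
    return headline_cases()


@pytest.fixture(scope="session")
def ax_ctx(cases):
    return cases["ax"]


@pytest.fixture(scope="session")
def ps_ctx(cases):
    return cases["ps"]


@pytest.fixture()
def default_geometry():
    return CorneaGeometry()


@pytest.fixture(scope="session")
def iso_spec():
    return MaterialSpec.isotropic("body", E=1.0e6, nu=0.3)


@pytest.fixture(scope="session")
def sector_mesh():
    return annular_sector_mesh(5.0, 7.0, n_r=6, n_t=12)


def circle_points(R, x_max=5.0, n=401, center_y=None, noise=0.0, rng=None):
    """Anterior-surface-like sample of a circle of radius R (apex at y=0)."""
    if center_y is None:
        center_y = -R
    x = np.linspace(-x_max, x_max, n)
    y = center_y + np.sqrt(R * R - x * x)
    if noise and rng is not None:
        y = y + rng.normal(0.0, noise, size=n)
    return np.column_stack([x, y])
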