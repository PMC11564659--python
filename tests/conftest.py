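import numpy as np
import pytest

from capsidtile.geometry import gnomonic_project, rotation_group, viper_axes
from capsidtile.tiling import JunctionPoint


@pytest.fixture(scope="session")
def axes():
    return viper_axes()


@pytest.fixture(scope="session")
def group(axes):
    return rotation_group(axes)


@pytest.fixture(scope="session")
def projected_triangle(axes):
    """Projected 2-, 3-, 5-fold axis points of the right-handed triangle."""
    return gnomonic_project(np.stack(axes.points()))


@pytest.fixture(scope="session")
def centroid_junction(projected_triangle):
    c = projected_triangle.mean(axis=0)
    return JunctionPoint(float(c[0]), float(c[1]), "right")


@pytest.fixture(scope="session")
def generic_junction(projected_triangle):
    """A generic interior junction, offset from the centroid."""
    c = projected_triangle.mean(axis=0)
    return JunctionPoint(float(c[0]) + 0.05, float(c[1]) + 0.03, "right")
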