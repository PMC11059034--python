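import numpy as np
import pytest

from uswinct.phantom import Ellipse, PhantomSpec, render_phantom
from uswinct.projection import FanBeamGeometry, forward_project


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_geom():
    """Desk-scale fan-beam geometry: 90 views, 64 detector cells."""
    return FanBeamGeometry(n_views=90, n_detectors=64, detector_spacing_mm=6.5, fov_mm=220.0)


@pytest.fixture(scope="session")
def fine_geom():
    """Finer geometry for reconstruction-accuracy checks."""
    return FanBeamGeometry(n_views=180, n_detectors=128, detector_spacing_mm=3.2, fov_mm=220.0)


@pytest.fixture(scope="session")
def disk_spec():
    """A static water disk (0 HU) of radius 0.25 FOV in air."""
    return PhantomSpec(components=(Ellipse((0.5, 0.5), (0.25, 0.25), 0.0, 0.0),))


@pytest.fixture(scope="session")
def disk_image(disk_spec):
    return render_phantom(disk_spec, 0.0, 64, 64)


@pytest.fixture(scope="session")
def disk_sinogram(disk_image, fine_geom):
    return forward_project(disk_image, fine_geom)
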