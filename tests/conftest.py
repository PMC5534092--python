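import numpy as np
import pytest

from lvdecomp import decompose, generate_study
from lvdecomp.geometry import PlanarContour
from lvdecomp.phantom import preset_spec


def circle_contour(radius, n=360, center=(0.0, 0.0)) -> PlanarContour:
    theta = np.arange(n) * (2 * np.pi / n)
    pts = np.stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)], axis=1
    )
    return PlanarContour(pts)


def ellipse_contour(a, b, n=720, center=(0.0, 0.0)) -> PlanarContour:
    theta = np.arange(n) * (2 * np.pi / n)
    pts = np.stack(
        [center[0] + a * np.cos(theta), center[1] + b * np.sin(theta)], axis=1
    )
    return PlanarContour(pts)


@pytest.fixture(scope="session")
def control_study():
    return generate_study(preset_spec("control"))


@pytest.fixture(scope="session")
def control_result(control_study):
    return decompose(control_study)


@pytest.fixture(scope="session")
def lad_result():
    return decompose(generate_study(preset_spec("lad")))
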