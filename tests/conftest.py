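import numpy as np
import pytest

from paleoshape.landmarks import LandmarkSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_landmarkset(rng, k=6, dim=2, specimen_id="s", template_id="t"):
    return LandmarkSet(specimen_id=specimen_id,
                       points=rng.standard_normal((k, dim)),
                       template_id=template_id)


def rotation_2d(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def circle_polygon(r=1.0, n=360, center=(0.0, 0.0)):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + r * np.cos(ang),
                     center[1] + r * np.sin(ang)], axis=1)
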