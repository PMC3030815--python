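import numpy as np
import pytest

from flight3d.geometry import CameraModel
from flight3d.synthetic import SimulationConfig, make_rig


@pytest.fixture
def canonical_camera():
    """P = [I | 0]: world frame == camera frame, unit focal length."""
    return CameraModel(id="canon", P=np.hstack([np.eye(3), np.zeros((3, 1))]))


@pytest.fixture
def focal_camera():
    """Focal length 100 px, principal point (320, 240), axis along +z."""
    K = np.array([[100.0, 0, 320], [0, 100.0, 240], [0, 0, 1]])
    return CameraModel(id="focal", P=K @ np.hstack([np.eye(3), np.zeros((3, 1))]),
                       image_size=(640, 480))


@pytest.fixture(scope="session")
def small_rig():
    """Default 5-camera rig around the 0.3 x 0.3 x 1.5 m arena."""
    return make_rig(SimulationConfig())


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig()


def random_camera(rng, focal_range=(200.0, 1500.0)):
    """A random full-rank finite camera with a proper rotation."""
    from scipy.spatial.transform import Rotation

    f = rng.uniform(*focal_range)
    K = np.array([[f, 0, rng.uniform(200, 500)],
                  [0, f, rng.uniform(150, 400)],
                  [0, 0, 1.0]])
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=2.0, size=(3, 1))
    return CameraModel(id="rand", P=K @ np.hstack([R, t]))
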