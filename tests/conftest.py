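import numpy as np
import pytest

from endofeat.synthetic import Ellipse, SceneSpec, generate_frame, random_scene

#: half-PAL frame size used throughout the suite to keep batteries fast
TEST_SHAPE = (288, 360)


def make_frame(seed: int, with_blood: bool = True, crisp: bool = False):
    """One randomized synthetic frame at test resolution."""
    spec = random_scene(seed, with_blood=with_blood, shape=TEST_SHAPE, crisp=crisp)
    return generate_frame(spec)


@pytest.fixture(scope="session")
def crisp_frame():
    """A deterministic frame with a single clean blood ellipse."""
    spec = SceneSpec(
        shape=TEST_SHAPE,
        fov_center=(144.0, 180.0),
        fov_radius=120.0,
        blood_blobs=(Ellipse(center=(150.0, 200.0), axes=(30.0, 45.0), angle=20.0),),
        seed=11,
    )
    return generate_frame(spec)


@pytest.fixture(scope="session")
def frame_battery():
    """Ten randomized frames (blood and non-blood) for invariant checks."""
    return [make_frame(seed, with_blood=seed % 2 == 0) for seed in range(10)]
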