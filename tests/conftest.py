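import numpy as np
import pytest

from skelpose import Anthropometry, SkeletonFrame, make_pose_template


@pytest.fixture
def anthro():
    return Anthropometry(height=1.80)


def frame_from_joints(joints, **kw):
    defaults = dict(timestamp=0.0, camera_id=0, subject_id="s01",
                    tracked=True, frame="room")
    defaults.update(kw)
    return SkeletonFrame(joints=np.asarray(joints, dtype=float), **defaults)


@pytest.fixture
def standing_frame(anthro):
    return frame_from_joints(make_pose_template(1, anthro, rng_seed=0))


def random_tracked_frame(rng, anthro=None):
    """A pose sampled from a random class with random placement."""
    if anthro is None:
        anthro = Anthropometry(height=float(rng.uniform(1.55, 1.90)))
    cls = int(rng.integers(1, 5))
    joints = make_pose_template(
        cls, anthro, rng, location=(float(rng.uniform(1, 3)), float(rng.uniform(1, 3))),
        heading=float(rng.uniform(0, 360)))
    return frame_from_joints(joints)
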