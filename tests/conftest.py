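import logging

import numpy as np
import pytest

import limotrack as lt
from limotrack import fusion, simulate as sim

logging.getLogger("limotrack").setLevel(logging.ERROR)
logging.getLogger("limotrack.legtrack").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def skeleton():
    return lt.build_skeleton(1.80)


@pytest.fixture(scope="session")
def skeleton_175():
    return lt.build_skeleton(1.75)


@pytest.fixture(scope="session")
def walk_session(skeleton_175):
    """5 s noise-free walk with lidar clouds (shared; do not mutate)."""
    return sim.simulate_session("walk", 5.0, skeleton_175, seed=1)


@pytest.fixture(scope="session")
def walk_foot_track(walk_session, skeleton_175):
    cfg = fusion.FusionConfig()
    aligned = lt.align_quaternions(walk_session.imu_stream)
    axes = fusion._shin_axes_for_frames(aligned, skeleton_175,
                                        walk_session.cloud_frames)
    return fusion.build_foot_track(walk_session.cloud_frames,
                                   walk_session.reference, skeleton_175,
                                   cfg, seed=3, shin_axes=axes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_unit_quaternions(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)
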