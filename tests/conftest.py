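import numpy as np
import pytest

from limbkin.synthetic_rig import (
    SensorErrorModel,
    make_scene,
    make_single_joint_trajectory,
)


@pytest.fixture(scope="session")
def noise_free_elbow_scene():
    """Noise-free rigid-arm scene: one 90-degree elbow flexion movement,
    random sensor mountings, full calibration item set."""
    traj = make_single_joint_trajectory("elbow_flexion", 90.0)
    return make_scene(
        tasks={"movement": traj}, error_model=SensorErrorModel.none(), seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
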