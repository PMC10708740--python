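import numpy as np
import pytest

from ergofatigue.fixtures import load_table
from ergofatigue.kinematics import ANGLE_CHANNELS, JointAngleFrame


@pytest.fixture(scope="session")
def table2_matrix() -> np.ndarray:
    return load_table("table2_scores").values


@pytest.fixture(scope="session")
def table1_rso2() -> np.ndarray:
    return load_table("table1_rso2_diff").values[:, 0]


@pytest.fixture(scope="session")
def table4_fatigue() -> np.ndarray:
    return load_table("table4_fatigue").values[:, 0]


@pytest.fixture(scope="session")
def table6_mee() -> np.ndarray:
    return load_table("table6_mee").values[:, 0]


def make_frame(time: float = 0.0, walking: bool = False, both_feet: bool = True,
               **overrides) -> JointAngleFrame:
    """A neutral standing posture with selected channels overridden."""
    angles = {k: 0.0 for k in ANGLE_CHANNELS}
    angles.update(overrides)
    return JointAngleFrame(
        time=time, angles=angles, both_feet_on_ground=both_feet, walking=walking
    )


@pytest.fixture
def neutral_frame() -> JointAngleFrame:
    return make_frame()
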