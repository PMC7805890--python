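import numpy as np
import pytest
from hypothesis import settings

from barntrack import (DetectionMap, OwnershipField, StateSpace,
                       motion_model_from_kernel)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def line3_space():
    """Three collinear cells, one orientation bin."""
    return StateSpace(n_x=3, n_y=1, cell_size=1.0, n_orient=1)


@pytest.fixture
def micro_scene(line3_space):
    """Single object on 3 cells: stay 0.6 / step 0.2 kernel, p = (0.7, 0.3, 0).

    The detection map for the next frame is (0.5, 0.8, 0.1).
    """
    kernel = np.zeros((3, 3, 1))
    kernel[1, 1, 0] = 0.6
    kernel[1, 0, 0] = 0.2
    kernel[1, 2, 0] = 0.2
    model = motion_model_from_kernel(line3_space, kernel, pos_radius=1,
                                     orient_radius=0)
    field = OwnershipField.empty(line3_space, frame_index=0)
    field.owner[:] = 0
    field.prob[0, :, 0] = [0.7, 0.3, 0.0]
    dmap = DetectionMap(frame_index=1,
                        values=np.array([0.5, 0.8, 0.1]).reshape(1, 3, 1))
    return line3_space, model, field, dmap
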