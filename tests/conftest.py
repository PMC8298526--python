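import numpy as np
import pytest

from woundlab.io import Calibration
from woundlab.tracks import TrackedCell


@pytest.fixture
def edge_calibration():
    return Calibration(pixel_size=0.2, frame_interval=3.7)


def make_track(points, wound_deg=0.0, cell_id="c1", dt=1.0):
    """TrackedCell from a list of (x, y) μm points, one per dt hours."""
    pts = np.asarray(points, float)
    return TrackedCell(
        cell_id=cell_id,
        t=np.arange(len(pts)) * dt,
        x=pts[:, 0],
        y=pts[:, 1],
        wound_direction_deg=wound_deg,
    )


@pytest.fixture
def straight_track():
    """10 points stepping 1 μm per frame along +x."""
    return make_track([(i, 0.0) for i in range(10)])
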