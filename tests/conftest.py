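import numpy as np
import pytest

from deglukin.trajectory_io import (
    EventLog,
    FrameAnnotation,
    PixelPoint,
    Recording,
)


def make_recording(rows, fps=30.0, events=None):
    """Build a Recording from (frame, marker, u, v) tuples."""
    by_frame = {}
    for frame, marker, u, v in rows:
        by_frame.setdefault(frame, {})[marker] = PixelPoint(u, v)
    frames = [FrameAnnotation(i, by_frame[i]) for i in sorted(by_frame)]
    return Recording(fps=fps, frames=frames, events=events or EventLog())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_recording():
    """Five static frames with coin, cervical landmarks and a hyoid."""
    rows = []
    for i in range(5):
        rows += [
            (i, "coin_a", 10.0, 10.0),
            (i, "coin_b", 34.0, 10.0),
            (i, "c2", 100.0, 180.0),
            (i, "c4", 100.0, 200.0),
            (i, "hyoid", 80.0, 190.0),
        ]
    return make_recording(rows)
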