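"""Shared fixtures: synthetic landmark faces and small binary streams."""

import numpy as np
import pytest

from drowsemeter.stream import StateStream


def make_face(right_pair_gaps=(6.0, 6.0), left_pair_gaps=(6.0, 6.0),
              mouth_heights=(7.0, 7.0, 7.0), mouth_width=10.0,
              center=(100.0, 100.0)):
    """A synthetic frontal 68-point landmark array (1-based iBUG layout).

    Eyes sit above the mouth (image y grows downward); the eyelid pair
    gaps, inner-lip heights and mouth width are set exactly so geometric
    expectations can be computed by hand.
    """
    cx, cy = center
    pts = np.zeros((68, 2))
    # benign filler for unused indices: a circle around the face center
    ang = np.linspace(0, 2 * np.pi, 68, endpoint=False)
    pts[:, 0] = cx + 40 * np.cos(ang)
    pts[:, 1] = cy + 40 * np.sin(ang)

    def put(idx, x, y):
        pts[idx - 1] = (x, y)

    eye_y = cy - 20.0
    # right eye (image left): upper lids 38, 39; lower lids 42, 41
    for (u, l), gap, x in zip(((38, 42), (39, 41)), right_pair_gaps, (cx - 18, cx - 12)):
        put(u, x, eye_y - gap / 2)
        put(l, x, eye_y + gap / 2)
    put(37, cx - 22, eye_y)
    put(40, cx - 8, eye_y)
    # left eye: upper lids 44, 45; lower lids 48, 47
    for (u, l), gap, x in zip(((44, 48), (45, 47)), left_pair_gaps, (cx + 12, cx + 18)):
        put(u, x, eye_y - gap / 2)
        put(l, x, eye_y + gap / 2)
    put(43, cx + 8, eye_y)
    put(46, cx + 22, eye_y)
    # inner lips: upper 62, 63, 64; lower 68, 67, 66; corners 61, 65
    mouth_y = cy + 30.0
    put(61, cx - mouth_width / 2, mouth_y)
    put(65, cx + mouth_width / 2, mouth_y)
    for (u, l), h, x in zip(((62, 68), (63, 67), (64, 66)), mouth_heights,
                            (cx - 3, cx, cx + 3)):
        put(u, x, mouth_y - h / 2)
        put(l, x, mouth_y + h / 2)
    return pts


@pytest.fixture
def face_points():
    return make_face()


def binary_stream(closed, mouth=None, fps=30.0):
    """StateStream from plain bool sequences (both eyes share ``closed``)."""
    closed = np.asarray(closed, dtype=bool)
    if mouth is None:
        mouth = np.zeros_like(closed)
    t = np.arange(closed.size) / fps
    return StateStream.from_arrays(t, nominal_fps=fps,
                                   left_closed=closed, right_closed=closed.copy(),
                                   mouth_open=np.asarray(mouth, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
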