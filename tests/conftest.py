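import numpy as np
import pytest

from smt2state.track_io import Detection, Track, TrackSet


def make_track(track_id, coords, start_frame=0, frames=None):
    """Track from a list of (x, y); frames consecutive unless given."""
    if frames is None:
        frames = range(start_frame, start_frame + len(coords))
    dets = [Detection(frame=f, x=float(x), y=float(y)) for f, (x, y) in zip(frames, coords)]
    return Track(track_id=track_id, detections=dets)


def stationary_track(track_id, n, x=0.0, y=0.0):
    return make_track(track_id, [(x, y)] * n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trackset():
    """Three tracks of lengths 4, 5, 6 with 0.1 µm x-steps."""
    tracks = [
        make_track("a", [(0.1 * i, 0.0) for i in range(4)]),
        make_track("b", [(0.1 * i, 1.0) for i in range(5)]),
        make_track("c", [(0.1 * i, 2.0) for i in range(6)]),
    ]
    return TrackSet(tracks=tracks, frame_interval=0.02, localization_precision=0.0)
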