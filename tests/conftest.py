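import numpy as np
import pytest

from trichamber import ArenaGeometry, TrialRecord, make_track
from trichamber.pose_io import BODYPARTS


@pytest.fixture(scope="session")
def geom():
    return ArenaGeometry()


def build_track(
    n_frames,
    frame_rate_hz=35.0,
    default_xy=(150.0, 150.0),
    coords=None,
    confidences=None,
):
    """A minimal valid track: every body part static at ``default_xy`` unless
    overridden by per-bodypart (n, 2) coordinate or (n,) confidence arrays."""
    coords = coords or {}
    confidences = confidences or {}
    xy = {}
    conf = {}
    for bp in BODYPARTS:
        if bp in coords:
            xy[bp] = np.asarray(coords[bp], float)
        else:
            xy[bp] = np.tile(np.asarray(default_xy, float), (n_frames, 1))
        if bp in confidences:
            conf[bp] = np.asarray(confidences[bp], float)
        else:
            conf[bp] = np.full(n_frames, 0.99)
    return make_track(xy, conf, frame_rate_hz)


@pytest.fixture
def track_factory():
    return build_track


@pytest.fixture
def soc_record():
    return TrialRecord(
        animal_id="a1",
        sex="F",
        generation="F1",
        lineage="NA",
        treatment_first="DMSO",
        treatment_second="NA",
        phase="sociability",
        stimulus_side="left",
        frame_rate_hz=35.0,
        litter_id="L1",
    )


@pytest.fixture
def nov_record():
    return TrialRecord(
        animal_id="a1",
        sex="M",
        generation="F1",
        lineage="NA",
        treatment_first="DMSO",
        treatment_second="NA",
        phase="social_novelty",
        stimulus_side="left",
        frame_rate_hz=35.0,
        litter_id="L1",
    )
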