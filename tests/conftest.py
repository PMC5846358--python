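import numpy as np
import pytest

from daphmove.features import build_feature_matrix
from daphmove.synthetic import ARCHETYPES, generate_segment
from daphmove.tracks import Arena, Track, as_segment


@pytest.fixture
def big_arena():
    """A large arena so hand-built geometric segments never hit walls."""
    return Arena(1000.0, 1000.0)


def make_track(points, arena, dt=0.25, subject_id="test", phase="before"):
    """Track from a list of (x, y) points on a uniform time grid."""
    points = np.asarray(points, float)
    return Track(
        subject_id=subject_id,
        phase=phase,
        t=np.arange(len(points)) * dt,
        x=points[:, 0],
        y=points[:, 1],
        arena=arena,
        frame_interval=dt,
    )


def make_segment(points, arena, dt=0.25):
    return as_segment(make_track(points, arena, dt=dt))


def archetype_dataset(n_per_class, rng):
    """Feature matrix + archetype labels from the default generator."""
    segs, labels = [], []
    for name, params in ARCHETYPES.items():
        for _ in range(n_per_class):
            segs.append(generate_segment(params, rng=rng))
            labels.append(name)
    return build_feature_matrix(segs), np.array(labels)
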