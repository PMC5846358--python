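"""The seven instantaneous movement parameters of a 5-s track segment.

For each inter-frame interval the step distance, heading and speed are
computed (:func:`step_geometry`); the seven segment-level parameters are
aggregates of these steps:

``speed``
    total distance / elapsed time (mm/s).
``acceleration``
    mean absolute step-speed change per frame interval (mm/s^2).
``locomotory_rate``
    distance while moving / moving time, i.e. the speed with stop time
    excluded from the denominator (mm/s); 0 if the animal never moves.
``stop_number``
    count of stop bouts — maximal runs of consecutive steps slower than
    the stop threshold.
``stop_time``
    total stopped duration (s).
``turning_rate``
    summed absolute heading change / elapsed time (rad/s).
``meander``
    summed absolute heading change / total distance (rad/mm); 0 for a
    stationary segment.

Heading changes are wrapped to (-pi, pi]. A zero-length step has no
heading; heading changes touching such a step contribute zero angle so
that the feature matrix stays dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Segment

#: Feature order used throughout the package (files, SOM, naming rules).
FEATURE_NAMES = (
    "speed",
    "acceleration",
    "locomotory_rate",
    "stop_number",
    "stop_time",
    "turning_rate",
    "meander",
)

#: Metadata columns of a feature matrix.
META_COLUMNS = ("subject_id", "phase", "segment")

#: Default stop-speed threshold, mm/s (about one pixel of tracking jitter
#: per frame at the reference system's resolution).
DEFAULT_STOP_THRESHOLD = 1.0


@dataclass(frozen=True)
class StepGeometry:
    """Per-interval kinematics of a segment."""

    distances: np.ndarray  # mm, one per inter-frame interval
    headings: np.ndarray  # rad, NaN where the step has zero length
    step_speeds: np.ndarray  # mm/s
    defined: np.ndarray  # bool, heading defined (non-zero step)


@dataclass(frozen=True)
class FeatureVector:
    speed: float
    acceleration: float
    locomotory_rate: float
    stop_number: int
    stop_time: float
    turning_rate: float
    meander: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], float)


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(a, dtype=float)))


def step_geometry(segment: Segment) -> StepGeometry:
    """Per-interval distance, heading and speed of a segment.

    Requires at least 3 frames (two steps), the minimum for any
    acceleration or turning quantity.
    """
    if segment.n_frames < 3:
        raise ValueError(
            f"segment has {segment.n_frames} frames; need at least 3"
        )
    dx = np.diff(segment.x)
    dy = np.diff(segment.y)
    distances = np.hypot(dx, dy)
    defined = distances > 0.0
    headings = np.where(defined, np.arctan2(dy, dx), np.nan)
    step_speeds = distances / segment.frame_interval
    return StepGeometry(distances, headings, step_speeds, defined)


def _heading_changes(geom: StepGeometry) -> np.ndarray:
    """Absolute wrapped heading change per consecutive step pair.

    Pairs touching an undefined heading contribute zero.
    """
    h = geom.headings
    ok = geom.defined[:-1] & geom.defined[1:]
    raw = np.where(ok, h[1:] - h[:-1], 0.0)
    return np.abs(wrap_angle(raw))


def compute_features(
    segment: Segment,
    stop_speed_threshold: float = DEFAULT_STOP_THRESHOLD,
) -> FeatureVector:
    """Compute the seven movement parameters of one segment.

    A step is "stopped" iff its speed is below ``stop_speed_threshold``.
    """
    if stop_speed_threshold < 0:
        raise ValueError("stop_speed_threshold must be non-negative")
    geom = step_geometry(segment)
    dt = segment.frame_interval
    elapsed = segment.duration
    total_dist = float(geom.distances.sum())

    speed = total_dist / elapsed

    dv = np.abs(np.diff(geom.step_speeds))
    acceleration = float(dv.mean()) / dt

    stopped = geom.step_speeds < stop_speed_threshold
    n_stopped = int(stopped.sum())
    stop_time = n_stopped * dt
    # stop bouts: maximal runs of consecutive stopped steps
    stop_number = int(
        stopped[0] + (np.diff(stopped.astype(int)) == 1).sum()
    ) if n_stopped else 0

    moving_time = elapsed - stop_time
    moving_dist = float(geom.distances[~stopped].sum())
    locomotory_rate = moving_dist / moving_time if moving_time > 0 else 0.0

    turn = float(_heading_changes(geom).sum())
    turning_rate = turn / elapsed
    meander = turn / total_dist if total_dist > 0 else 0.0

    return FeatureVector(
        speed=speed,
        acceleration=acceleration,
        locomotory_rate=locomotory_rate,
        stop_number=stop_number,
        stop_time=stop_time,
        turning_rate=turning_rate,
        meander=meander,
    )


def build_feature_matrix(
    segments: list[Segment],
    stop_speed_threshold: float = DEFAULT_STOP_THRESHOLD,
    n_sample: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One feature row per segment, with subject/phase/segment metadata.

    ``n_sample`` subsamples rows uniformly without replacement with a
    fixed seed (the reference analysis trains on 1000 segments per
    phase); the original row order is preserved.
    """
    if not segments:
        raise ValueError("no segments given")
    dts = {s.frame_interval for s in segments}
    if len(dts) > 1:
        raise ValueError(f"segments mix frame intervals: {sorted(dts)}")
    rows = []
    for i, seg in enumerate(segments):
        fv = compute_features(seg, stop_speed_threshold)
        rows.append(
            {
                "subject_id": seg.track.subject_id,
                "phase": seg.track.phase,
                "segment": seg.index if seg.index is not None else i,
                **{name: getattr(fv, name) for name in FEATURE_NAMES},
            }
        )
    df = pd.DataFrame(rows)
    if n_sample is not None:
        if not 0 < n_sample <= len(df):
            raise ValueError(f"n_sample={n_sample} not in [1, {len(df)}]")
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(df), size=n_sample, replace=False))
        df = df.iloc[keep].reset_index(drop=True)
    return df


def write_features(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in (*META_COLUMNS, *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    return df
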