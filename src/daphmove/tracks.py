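"""Trajectory data model, CSV I/O and fixed-window segmentation.

A :class:`Track` is the position stream of one animal recorded at a fixed
frame interval (0.25 s in the reference observation system) inside a
rectangular arena. Analyses operate on :class:`Segment` windows cut from a
track: short 5-s windows for movement-pattern features and long 10-min
windows for fractal-dimension estimation.

Coordinates are continuous millimetres with the origin at the arena's
lower-left corner and y increasing upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Recording phases relative to the chemical treatment.
PHASES = ("before", "after")

#: Default frame interval of the observation system, seconds.
DEFAULT_FRAME_INTERVAL = 0.25

#: Columns of the on-disk track format.
TRACK_COLUMNS = ("frame", "t_s", "x_mm", "y_mm")

_TIME_TOL = 1e-9
_BOUND_TOL = 1e-9


class TrackError(ValueError):
    """Base class for track I/O and validation failures."""


class TrackParseError(TrackError):
    """A track file row could not be parsed."""


class TrackValidationError(TrackError):
    """A track violates an invariant (bounds, time grid, size)."""


@dataclass(frozen=True)
class Arena:
    """Rectangular observation arena, dimensions in mm.

    Defaults to the 60 mm x 50 mm cage of the reference recording setup
    (cage depth is not modelled; tracking is two-dimensional).
    """

    width: float = 60.0
    height: float = 50.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("arena dimensions must be positive")


@dataclass
class Track:
    """One animal's timestamped 2-D trajectory in a bounded arena.

    Invariants (checked on construction): at least 2 points, strictly
    increasing timestamps on a uniform ``frame_interval`` grid (to 1e-9 s),
    and all coordinates inside the arena. Tracking dropouts (missing
    frames) are rejected rather than imputed.
    """

    subject_id: str
    phase: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena: Arena = field(default_factory=Arena)
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise TrackValidationError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.ndim == self.x.ndim == self.y.ndim == 1):
            raise TrackValidationError("t, x, y must be 1-D arrays")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise TrackValidationError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise TrackValidationError("a track needs at least 2 points")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise TrackValidationError(
                f"timestamps not strictly increasing at frame {i + 1}"
            )
        bad = np.abs(dt - self.frame_interval) > _TIME_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise TrackValidationError(
                f"non-uniform time step at frame {i + 1}: "
                f"dt={dt[i]:.9g}s, expected {self.frame_interval:.9g}s "
                "(tracking gaps are not supported)"
            )
        for name, vals, hi in (
            ("x", self.x, self.arena.width),
            ("y", self.y, self.arena.height),
        ):
            out = (vals < -_BOUND_TOL) | (vals > hi + _BOUND_TOL)
            if np.any(out):
                i = int(np.argmax(out))
                raise TrackValidationError(
                    f"{name}={vals[i]:.6g} mm outside arena [0, {hi:g}] "
                    f"at frame {i}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Elapsed recording time in seconds."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class Segment:
    """Half-open frame window ``[start, end)`` of a parent track.

    ``duration`` is elapsed time, i.e. ``(end - start - 1) * frame_interval``
    (fence-post: a 21-frame window at 0.25 s/frame spans exactly 5 s).
    """

    track: Track
    start: int
    end: int
    index: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= self.track.n_frames):
            raise ValueError(
                f"segment [{self.start}, {self.end}) outside track of "
                f"{self.track.n_frames} frames"
            )
        if self.end - self.start < 2:
            raise ValueError("a segment needs at least 2 frames")

    @property
    def t(self) -> np.ndarray:
        return self.track.t[self.start : self.end]

    @property
    def x(self) -> np.ndarray:
        return self.track.x[self.start : self.end]

    @property
    def y(self) -> np.ndarray:
        return self.track.y[self.start : self.end]

    @property
    def arena(self) -> Arena:
        return self.track.arena

    @property
    def frame_interval(self) -> float:
        return self.track.frame_interval

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    @property
    def duration(self) -> float:
        return (self.end - self.start - 1) * self.track.frame_interval


def as_segment(track: Track, index: int | None = None) -> Segment:
    """View a whole track as a single segment."""
    return Segment(track, 0, track.n_frames, index=index)


def read_track(
    path: str | Path,
    phase: str,
    arena: Arena | None = None,
    subject_id: str | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> Track:
    """Read one track from a ``frame,t_s,x_mm,y_mm`` CSV file.

    Rows are sorted by time before validation. Raises
    :class:`TrackParseError` naming the offending line for malformed rows
    and :class:`TrackValidationError` for out-of-arena coordinates or a
    non-uniform time grid.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise TrackParseError(f"{path}: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"{path}: missing columns {missing}")
    numeric = {}
    for col in TRACK_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or vals.isna().any():
            row = int(np.argmax((bad | vals.isna()).to_numpy()))
            # +2: one for the header line, one for 1-based numbering
            raise TrackParseError(
                f"{path}: cannot parse column {col!r} at line {row + 2}"
            )
        numeric[col] = vals.to_numpy()
    order = np.argsort(numeric["t_s"], kind="stable")
    return Track(
        subject_id=subject_id if subject_id is not None else path.stem,
        phase=phase,
        t=numeric["t_s"][order],
        x=numeric["x_mm"][order],
        y=numeric["y_mm"][order],
        arena=arena if arena is not None else Arena(),
        frame_interval=frame_interval,
    )


def write_track(track: Track, path: str | Path) -> None:
    """Write a track as CSV, round-trippable to better than 1e-6 mm."""
    if not isinstance(track, Track):
        raise TrackValidationError("write_track expects a Track")
    df = pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "t_s": track.t,
            "x_mm": track.x,
            "y_mm": track.y,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def segment_track(
    track: Track,
    window_s: float,
    n_sample: int | None = None,
    seed: int | None = None,
) -> list[Segment]:
    """Cut a track into consecutive non-overlapping analysis windows.

    Windows advance by ``window_s / frame_interval`` intervals and each
    window re-reads its boundary frame, i.e. window k covers frames
    ``[k*m, k*m + m + 1)`` with ``m = window_s / frame_interval``, so each
    spans exactly ``window_s`` of elapsed time and per-interval quantities
    are never double counted. A trailing partial window is discarded.

    ``n_sample`` optionally draws that many windows uniformly without
    replacement (seeded), preserving temporal order — for analyses that
    sample rather than exhaust the recording.
    """
    dt = track.frame_interval
    if window_s < 2 * dt:
        raise ValueError(
            f"window_s={window_s:g}s too short: needs at least two frame "
            f"intervals ({2 * dt:g}s) to contain one movement step"
        )
    m = window_s / dt
    if abs(m - round(m)) > 1e-9:
        raise ValueError(
            f"window_s={window_s:g}s is not a multiple of the frame "
            f"interval {dt:g}s"
        )
    m = int(round(m))
    n_windows = (track.n_frames - 1) // m
    if n_windows == 0:
        raise ValueError(
            f"track ({track.duration:g}s) shorter than one {window_s:g}s window"
        )
    indices = np.arange(n_windows)
    if n_sample is not None:
        if not 0 < n_sample <= n_windows:
            raise ValueError(
                f"n_sample={n_sample} not in [1, {n_windows}] windows"
            )
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(n_windows, size=n_sample, replace=False))
    return [Segment(track, k * m, k * m + m + 1, index=int(k)) for k in indices]
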