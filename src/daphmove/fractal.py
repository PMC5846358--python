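"""Box-counting fractal dimension of rasterized movement tracks.

The complexity of a long (10-min) movement track is summarized by the
box-counting dimension

    D = lim_{delta -> 0} log N(delta) / log(1/delta),

where N(delta) is the number of axis-aligned boxes of side ``delta``
(pixels) that intersect the track on an M x M binary raster, M a power
of 2. In practice D is the least-squares slope of log N(delta) against
log(1/delta) over a dyadic schedule of box sizes. For 2-D tracks D lies
between 1.0 (a straight line) and 2.0 (a track that fills the arena
surface evenly); a drop in D signals reduced movement complexity.

Rasterization is isotropic (one mm-per-pixel factor for both axes,
anchored at the arena origin): stretching a non-square arena onto a
square raster would distort angles and bias the dimension. Consecutive
samples are joined by Bresenham line segments by default, since at
0.25 s sampling the raw positions are disconnected dots whose fine-scale
box counts collapse; ``mode="points"`` disables the interpolation.

Scales where the count saturates (N=1, or every box occupied) carry no
slope information; they are excluded before fitting. If fewer than three
scales survive, saturated scales are re-admitted (then N=1 scales), so
that the topological limit cases — a full surface (all scales saturated,
slope exactly 2) and a single point (slope 0) — remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _bresenham_line

from .tracks import Segment, Track, segment_track

RASTER_MODES = ("lines", "points")


class FractalFitError(ValueError):
    """Too few usable scales to fit a dimension."""


@dataclass
class BinaryTrackImage:
    """M x M boolean occupancy raster of a track, M a power of 2."""

    grid: np.ndarray
    mm_per_pixel: float

    @property
    def size(self) -> int:
        return self.grid.shape[0]


@dataclass
class BoxCountSeries:
    """Occupied-box counts N(delta) over increasing box sizes."""

    deltas: np.ndarray
    counts: np.ndarray
    M: int


@dataclass
class FractalResult:
    """Fitted dimension with the (log(1/delta), log N) points used."""

    D: float
    fit_points: np.ndarray  # (n, 2) columns log(1/delta), log N(delta)
    r_squared: float

    @property
    def n_fit_points(self) -> int:
        return len(self.fit_points)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def rasterize(
    obj: Track | Segment,
    M: int = 256,
    mode: str = "lines",
) -> BinaryTrackImage:
    """Rasterize a track or segment onto an M x M binary grid.

    Scale is ``(M - 1) / max(arena.width, arena.height)`` so the larger
    arena dimension maps onto the full pixel range. With ``mode="lines"``
    every pixel on the Bresenham line between consecutive samples is
    occupied, making the image 8-connected.
    """
    if not _is_power_of_two(M) or M < 8:
        raise ValueError(f"M={M} must be a power of 2, at least 8")
    if mode not in RASTER_MODES:
        raise ValueError(f"mode must be one of {RASTER_MODES}")
    arena = obj.arena
    scale = (M - 1) / max(arena.width, arena.height)
    px = np.clip(np.rint(np.asarray(obj.x) * scale).astype(int), 0, M - 1)
    py = np.clip(np.rint(np.asarray(obj.y) * scale).astype(int), 0, M - 1)
    grid = np.zeros((M, M), dtype=bool)
    if mode == "points" or len(px) == 1:
        grid[py, px] = True
    else:
        for i in range(len(px) - 1):
            if px[i] == px[i + 1] and py[i] == py[i + 1]:
                grid[py[i], px[i]] = True
                continue
            rr, cc = _bresenham_line(py[i], px[i], py[i + 1], px[i + 1])
            grid[rr, cc] = True
    return BinaryTrackImage(grid=grid, mm_per_pixel=1.0 / scale)


def default_deltas(M: int) -> np.ndarray:
    """Dyadic box-size schedule {2, 4, ..., M/2}."""
    return 2 ** np.arange(1, int(np.log2(M)))


def box_counts(
    image: BinaryTrackImage,
    deltas: np.ndarray | list[int] | None = None,
) -> BoxCountSeries:
    """Count occupied boxes for each box size.

    The grid is partitioned into ``(M/delta)^2`` boxes anchored at the
    origin; a box counts if it contains at least one occupied pixel.
    """
    M = image.size
    if deltas is None:
        deltas = default_deltas(M)
    deltas = np.sort(np.asarray(deltas, dtype=int))
    if len(deltas) == 0:
        raise ValueError("empty box-size schedule")
    if np.any(deltas < 1) or np.any(M % deltas != 0):
        bad = deltas[(deltas < 1) | (M % deltas != 0)]
        raise ValueError(f"box sizes {bad.tolist()} do not divide M={M}")
    counts = np.empty(len(deltas), dtype=int)
    for i, d in enumerate(deltas):
        d = int(d)
        occupied = image.grid.reshape(M // d, d, M // d, d).any(axis=(1, 3))
        counts[i] = int(occupied.sum())
    # nested dyadic grids make N(delta) non-increasing in delta
    assert np.all(np.diff(counts) <= 0), "box counts not monotone"
    return BoxCountSeries(deltas=deltas, counts=counts, M=M)


def fit_dimension(series: BoxCountSeries) -> FractalResult:
    """Least-squares slope of log N(delta) vs log(1/delta).

    Saturated scales (N=1 or every box occupied) are excluded; the
    filter is relaxed stepwise if it would leave fewer than 3 scales
    (see module docstring). Raises :class:`FractalFitError` when the
    series itself has fewer than 3 scales.
    """
    deltas = np.asarray(series.deltas, dtype=float)
    counts = np.asarray(series.counts, dtype=float)
    if len(deltas) < 3:
        raise FractalFitError(
            f"saturation filter needs >= 3 scales, series has {len(deltas)}"
        )
    full = (series.M / deltas) ** 2
    usable = (counts > 1) & (counts < full)
    if usable.sum() < 3:
        usable = counts > 1  # re-admit saturated scales
    if usable.sum() < 3:
        usable = np.ones_like(usable, dtype=bool)  # re-admit N=1 scales
    x = np.log(1.0 / deltas[usable])
    y = np.log(counts[usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float((resid**2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FractalResult(
        D=float(slope),
        fit_points=np.column_stack([x, y]),
        r_squared=r_squared,
    )


def segment_dimension(
    obj: Track | Segment,
    M: int = 256,
    deltas=None,
    mode: str = "lines",
) -> FractalResult:
    """Rasterize one track/segment and fit its box-counting dimension."""
    return fit_dimension(box_counts(rasterize(obj, M=M, mode=mode), deltas))


def track_fractal_dimension(
    track: Track,
    window_s: float = 600.0,
    M: int = 256,
    deltas=None,
    mode: str = "lines",
    n_sample: int | None = None,
    seed: int | None = None,
) -> list[FractalResult]:
    """Fractal dimension of each ``window_s`` window of a track.

    Windows are consecutive by default; ``n_sample`` draws a seeded
    random subset instead.
    """
    segments = segment_track(track, window_s, n_sample=n_sample, seed=seed)
    return [segment_dimension(seg, M=M, deltas=deltas, mode=mode) for seg in segments]
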