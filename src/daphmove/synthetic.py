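"""Seeded synthetic movement tracks with known pattern composition.

The reference study's raw video-tracking data were never released, so
this module emulates them: a correlated random walk whose per-step speed
is truncated-normal and whose heading increments follow one of six
archetype regimes (line, loop, cross, shaking, swirl, stay), chained
into 5-s blocks to form full recording sessions with a prescribed
pattern composition. Block archetypes double as ground-truth labels for
classifier validation.

Archetype kinematics are calibration choices, anchored so that
phase-mean speeds and turning rates land near the reference study's
printed magnitudes (speed ~5 mm/s before, ~3.5 mm/s after; turning rate
a few rad/s) and so that the six archetypes are separable in the seven
movement parameters. The before/after compositions pin the two printed
percentages (P1 25.4% -> 17.1%, P6 14.7% -> 22.5%) exactly; the other
four patterns are implementer defaults scaled to fill the remainder.

Walls are handled by specular reflection of the heading at frame
granularity: a step that would exit the arena is re-aimed by flipping
the offending velocity component, so every stored step keeps its exact
length and all coordinates stay inside the arena.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .som import PATTERNS, PATTERN_ARCHETYPES
from .tracks import Arena, Segment, Track, as_segment

TURN_SIGN_MODES = ("fixed", "alternating", "none")

#: Block length matching the pattern-segmentation window, seconds.
BLOCK_S = 5.0


@dataclass(frozen=True)
class ArchetypeParams:
    """Correlated-random-walk parameters of one movement archetype.

    ``speed_mean``/``speed_sd`` (mm/s) set the truncated-normal step
    speed; ``turn_mean``/``turn_sd`` (rad/s) the heading increment,
    whose sign is constant per segment (``fixed``: loops and swirls),
    alternates every step (``alternating``: shaking), or is absent
    (``none``: zero-mean wander, straight for small ``turn_sd``).
    ``stop_fraction`` of the steps are forced below the stop-speed
    threshold as one contiguous stay bout.
    """

    pattern: str
    speed_mean: float
    speed_sd: float
    turn_mean: float
    turn_sd: float
    turn_sign_mode: str
    stop_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.turn_sign_mode not in TURN_SIGN_MODES:
            raise ValueError(
                f"turn_sign_mode must be one of {TURN_SIGN_MODES}"
            )
        if self.speed_mean < 0 or self.speed_sd < 0 or self.turn_sd < 0:
            raise ValueError("speed/turn parameters must be non-negative")
        if not 0.0 <= self.stop_fraction <= 1.0:
            raise ValueError("stop_fraction must lie in [0, 1]")


#: Default archetype kinematics (see module docstring on calibration).
ARCHETYPES: dict[str, ArchetypeParams] = {
    "line": ArchetypeParams("line", 9.0, 0.6, 0.0, 0.12, "none", 0.0),
    "loop": ArchetypeParams("loop", 5.5, 0.6, 3.0, 0.15, "fixed", 0.0),
    "cross": ArchetypeParams("cross", 5.0, 2.5, 0.0, 4.0, "none", 0.0),
    "shaking": ArchetypeParams("shaking", 3.0, 0.4, 6.0, 0.4, "alternating", 0.05),
    "swirl": ArchetypeParams("swirl", 1.5, 0.3, 3.0, 0.3, "fixed", 0.15),
    "stay": ArchetypeParams("stay", 0.2, 0.15, 0.0, 0.3, "none", 0.8),
}

#: Printed before/after proportions of P1 and P6; the free patterns
#: below are scaled so each composition sums to 1 without moving these.
_ANCHORS = {
    "before": {"P1": 0.254, "P6": 0.147},
    "after": {"P1": 0.171, "P6": 0.225},
}
_FREE_RAW = {
    "before": {"P2": 0.20, "P3": 0.15, "P4": 0.08, "P5": 0.07},
    "after": {"P2": 0.14, "P3": 0.10, "P4": 0.17, "P5": 0.19},
}


def default_composition(phase: str) -> dict[str, float]:
    """Default pattern composition of one phase (probabilities sum to 1)."""
    anchors = _ANCHORS[phase]
    free = _FREE_RAW[phase]
    scale = (1.0 - sum(anchors.values())) / sum(free.values())
    comp = {**anchors, **{p: v * scale for p, v in free.items()}}
    return {p: comp[p] for p in PATTERNS}


@dataclass(frozen=True)
class SessionSpec:
    """Specification of one synthetic recording session."""

    composition: dict[str, float]
    duration_s: float
    seed: int
    subject_id: str = "synthetic"
    phase: str = "before"
    arena: Arena = field(default_factory=Arena)
    frame_interval: float = 0.25
    archetypes: dict[str, ArchetypeParams] | None = None

    def __post_init__(self) -> None:
        if set(self.composition) != set(PATTERNS):
            raise ValueError(f"composition must cover exactly {PATTERNS}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total:.12g}, expected 1")
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition probabilities must be non-negative")
        n_blocks = self.duration_s / BLOCK_S
        if abs(n_blocks - round(n_blocks)) > 1e-9 or n_blocks < 1:
            raise ValueError(
                f"duration_s={self.duration_s:g} must be a positive "
                f"multiple of {BLOCK_S:g} s"
            )


def _walk(
    rng: np.random.Generator,
    params: ArchetypeParams,
    n_steps: int,
    dt: float,
    x0: float,
    y0: float,
    heading0: float,
    arena: Arena,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Advance one correlated-random-walk block; returns new points and
    the final heading (positions exclude the start point)."""
    speeds = np.clip(rng.normal(params.speed_mean, params.speed_sd, n_steps), 0.0, None)
    # keep steps far below the arena half-width so one reflection suffices
    max_speed = 0.45 * min(arena.width, arena.height) / dt
    speeds = np.minimum(speeds, max_speed)

    if params.turn_sign_mode == "none":
        dtheta = rng.normal(0.0, params.turn_sd, n_steps) * dt
    else:
        rates = rng.normal(params.turn_mean, params.turn_sd, n_steps)
        sign = rng.choice((-1.0, 1.0))
        if params.turn_sign_mode == "alternating":
            signs = sign * (-1.0) ** np.arange(n_steps)
        else:
            signs = np.full(n_steps, sign)
        dtheta = signs * rates * dt

    k_stop = int(round(params.stop_fraction * n_steps))
    if k_stop > 0:
        start = int(rng.integers(0, n_steps - k_stop + 1))
        speeds[start : start + k_stop] = rng.uniform(0.0, 0.3, k_stop)

    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    x, y, theta = x0, y0, heading0
    w, h = arena.width, arena.height
    for i in range(n_steps):
        theta += dtheta[i]
        L = speeds[i] * dt
        for _ in range(4):  # at most two reflections ever needed
            nx = x + L * np.cos(theta)
            ny = y + L * np.sin(theta)
            if nx < 0.0 or nx > w:
                theta = np.pi - theta
                continue
            if ny < 0.0 or ny > h:
                theta = -theta
                continue
            break
        else:  # pathological corner start; fold as a last resort
            nx = min(max(nx, 0.0), w)
            ny = min(max(ny, 0.0), h)
        x, y = nx, ny
        xs[i], ys[i] = x, y
    return xs, ys, float(theta)


def generate_segment(
    params: ArchetypeParams,
    duration_s: float = BLOCK_S,
    frame_interval: float = 0.25,
    start_pose: tuple[float, float, float] | None = None,
    arena: Arena | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "synthetic",
    phase: str = "before",
) -> Segment:
    """One archetype segment as a standalone single-block track."""
    arena = arena or Arena()
    if rng is None:
        rng = np.random.default_rng(seed)
    n_steps = int(round(duration_s / frame_interval))
    if n_steps < 2:
        raise ValueError("segment needs at least 2 steps")
    if start_pose is None:
        start_pose = (
            arena.width / 2.0,
            arena.height / 2.0,
            float(rng.uniform(-np.pi, np.pi)),
        )
    x0, y0, heading0 = start_pose
    xs, ys, _ = _walk(rng, params, n_steps, frame_interval, x0, y0, heading0, arena)
    track = Track(
        subject_id=subject_id,
        phase=phase,
        t=np.arange(n_steps + 1) * frame_interval,
        x=np.concatenate([[x0], xs]),
        y=np.concatenate([[y0], ys]),
        arena=arena,
        frame_interval=frame_interval,
    )
    return as_segment(track, index=0)


def generate_session_with_truth(spec: SessionSpec) -> tuple[Track, np.ndarray]:
    """One session track plus the true pattern label of each 5-s block."""
    rng = np.random.default_rng(spec.seed)
    archetypes = spec.archetypes or ARCHETYPES
    dt = spec.frame_interval
    steps_per_block = int(round(BLOCK_S / dt))
    n_blocks = int(round(spec.duration_s / BLOCK_S))
    probs = np.array([spec.composition[p] for p in PATTERNS])
    labels = rng.choice(PATTERNS, size=n_blocks, p=probs / probs.sum())

    n_points = 1 + n_blocks * steps_per_block
    xs = np.empty(n_points)
    ys = np.empty(n_points)
    x = spec.arena.width / 2.0
    y = spec.arena.height / 2.0
    theta = float(rng.uniform(-np.pi, np.pi))
    xs[0], ys[0] = x, y
    pos = 1
    for lab in labels:
        params = archetypes[PATTERN_ARCHETYPES[lab]]
        bx, by, theta = _walk(rng, params, steps_per_block, dt, x, y, theta, spec.arena)
        xs[pos : pos + steps_per_block] = bx
        ys[pos : pos + steps_per_block] = by
        x, y = bx[-1], by[-1]
        pos += steps_per_block
    track = Track(
        subject_id=spec.subject_id,
        phase=spec.phase,
        t=np.arange(n_points) * dt,
        x=xs,
        y=ys,
        arena=spec.arena,
        frame_interval=dt,
    )
    return track, labels


def generate_session(spec: SessionSpec) -> Track:
    """One session track (see :func:`generate_session_with_truth`)."""
    return generate_session_with_truth(spec)[0]


def jitter_composition(
    composition: dict[str, float],
    rng: np.random.Generator,
    sd: float = 0.015,
    floor: float = 0.005,
) -> dict[str, float]:
    """Per-subject compositional jitter: additive Gaussian noise on the
    probabilities, floored and renormalized."""
    vals = np.array([composition[p] for p in PATTERNS])
    vals = np.maximum(vals + rng.normal(0.0, sd, len(vals)), floor)
    vals /= vals.sum()
    return dict(zip(PATTERNS, vals))


def default_study_with_truth(
    seed: int,
    n_subjects: int = 10,
    duration_s: float = 86400.0,
    jitter_sd: float = 0.015,
    arena: Arena | None = None,
) -> tuple[list[Track], list[Track], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """The emulated study design with ground-truth block labels.

    ``n_subjects`` animals recorded for ``duration_s`` in each phase
    (the reference design: 10 animals, 24 h per phase), with the default
    before/after compositions and small per-subject compositional
    jitter. Returns (before_tracks, after_tracks, truth_before,
    truth_after); truths map subject_id to the block-label array.
    """
    arena = arena or Arena()
    ss = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    tracks: dict[str, list[Track]] = {"before": [], "after": []}
    truths: dict[str, dict[str, np.ndarray]] = {"before": {}, "after": {}}
    for i in range(n_subjects):
        subject = f"subject{i + 1:02d}"
        for phase in ("before", "after"):
            comp = jitter_composition(
                default_composition(phase), jitter_rng, sd=jitter_sd
            )
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            spec = SessionSpec(
                composition=comp,
                duration_s=duration_s,
                seed=child_seed,
                subject_id=subject,
                phase=phase,
                arena=arena,
            )
            track, labels = generate_session_with_truth(spec)
            tracks[phase].append(track)
            truths[phase][subject] = labels
    return tracks["before"], tracks["after"], truths["before"], truths["after"]


def default_study(
    seed: int,
    n_subjects: int = 10,
    duration_s: float = 86400.0,
    jitter_sd: float = 0.015,
    arena: Arena | None = None,
) -> tuple[list[Track], list[Track]]:
    """10 before / 10 after tracks of the emulated study (no truth labels)."""
    before, after, _, _ = default_study_with_truth(
        seed, n_subjects, duration_s, jitter_sd, arena
    )
    return before, after


# -- reference geometric tracks (analytic fractal-dimension limits) ----------


def diagonal_track(
    arena: Arena | None = None,
    n_frames: int = 1201,
    frame_interval: float = 0.25,
    subject_id: str = "diagonal",
    phase: str = "before",
) -> Track:
    """Constant-heading, constant-speed track spanning the arena diagonal.

    Its raster is a digital straight line, the D = 1.0 reference case.
    """
    arena = arena or Arena()
    frac = np.linspace(0.0, 1.0, n_frames)
    return Track(
        subject_id=subject_id,
        phase=phase,
        t=np.arange(n_frames) * frame_interval,
        x=frac * arena.width,
        y=frac * arena.height,
        arena=arena,
        frame_interval=frame_interval,
    )


def boustrophedon_track(
    M: int = 256,
    arena: Arena | None = None,
    frame_interval: float = 0.25,
    subject_id: str = "sweep",
    phase: str = "before",
) -> Track:
    """Serpentine sweep whose M-pixel raster occupies the whole grid.

    One horizontal pass per pixel row; the D = 2.0 (surface) reference
    case. Full-grid coverage requires a square arena (isotropic scaling
    leaves part of the grid unreachable otherwise), so the default is
    60 mm x 60 mm.
    """
    arena = arena or Arena(60.0, 60.0)
    if arena.width != arena.height:
        raise ValueError("a full-surface sweep needs a square arena")
    ys = np.arange(M) * arena.height / (M - 1)
    xs_list = []
    ys_list = []
    for k, yk in enumerate(ys):
        xpair = (0.0, arena.width) if k % 2 == 0 else (arena.width, 0.0)
        xs_list.extend(xpair)
        ys_list.extend((yk, yk))
    n = len(xs_list)
    return Track(
        subject_id=subject_id,
        phase=phase,
        t=np.arange(n) * frame_interval,
        x=np.array(xs_list),
        y=np.array(ys_list),
        arena=arena,
        frame_interval=frame_interval,
    )


# -- YAML study configuration -------------------------------------------------


def load_study_config(path: str | Path) -> dict:
    """Load composition tables and archetype overrides from YAML.

    Recognized keys: ``compositions: {before: {P1: ...}, after: ...}``
    and ``archetypes: {line: {speed_mean: ...}, ...}`` (partial
    overrides of the defaults).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    compositions = {
        "before": default_composition("before"),
        "after": default_composition("after"),
    }
    for phase, table in (raw.get("compositions") or {}).items():
        if phase not in compositions:
            raise ValueError(f"unknown phase {phase!r} in {path}")
        compositions[phase] = {p: float(table[p]) for p in PATTERNS}
    archetypes = dict(ARCHETYPES)
    for name, overrides in (raw.get("archetypes") or {}).items():
        if name not in archetypes:
            raise ValueError(f"unknown archetype {name!r} in {path}")
        archetypes[name] = replace(archetypes[name], **overrides)
    return {"compositions": compositions, "archetypes": archetypes}
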