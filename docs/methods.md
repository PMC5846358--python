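# Methods

This note documents the models and procedures implemented in `daphmove`,
the defaults they use, and the choices made where the design was open.

## Track model and segmentation

A track is one animal's position stream `(t, x, y)` in millimetres inside a
rectangular arena (default 60 mm × 50 mm, the observation-cage footprint of
the assay this pipeline targets), sampled at a fixed 0.25 s frame interval.
Coordinates use the arena's lower-left corner as origin, y upward.
Timestamps must sit on the uniform grid to 1e-9 s; tracking dropouts are a
validation error, not imputed — the pipeline assumes continuous recognition,
and silently bridging gaps would bias every per-step quantity.

Analysis windows are consecutive, non-overlapping in elapsed time, and
boundary-frame sharing is deliberate: a 5-s window at 0.25 s/frame holds 21
frames (20 inter-frame intervals, fence-post counting), and window *k*
covers frames `[20k, 20k + 21)`. The shared boundary frame makes each
window span exactly 5 s; all features are aggregates of *intervals*, so
nothing is double-counted. A trailing partial window is discarded. Two
window lengths matter downstream: 5 s for pattern features, 600 s for
fractal dimension. For the long windows both exhaustive (default) and
seeded random subsets of windows are supported, since recordings can be
analysed either way.

Behaviors faster than one frame interval (e.g. sub-0.25 s trembling) are
outside the model's resolution and out of scope.

## The seven movement parameters

Per inter-frame interval the step distance, heading (atan2 of the
displacement) and step speed are computed. A zero-length step has no
heading; heading changes touching it contribute zero angle, keeping the
feature matrix dense. Heading changes are wrapped to (−π, π].

Per 5-s segment:

| parameter | definition | units |
|---|---|---|
| speed | total distance / elapsed time | mm/s |
| acceleration | mean \|Δ step speed\| / frame interval | mm/s² |
| locomotory rate | distance while moving / moving time | mm/s |
| stop number | count of maximal runs of stopped steps | – |
| stop time | stopped steps × frame interval | s |
| turning rate | Σ \|wrapped heading change\| / elapsed time | rad/s |
| meander | Σ \|wrapped heading change\| / total distance | rad/mm |

A step is *stopped* when its speed falls below a threshold (default
1.0 mm/s, about one pixel of tracking jitter per frame at typical video
resolution; exposed as `--stop-threshold`). "Without movement" has no
universal quantitative definition, so the threshold is configurable.
Locomotory rate is 0 when the animal never moves; meander is 0 for a
stationary segment. Acceleration is aggregated as the mean absolute per-step
value because the classifier needs one non-negative scalar per segment;
turning quantities are magnitudes (unsigned), since the analysis direction
of interest is "more turning under stress", not its handedness.

These definitions make every feature invariant under rigid motion of the
segment (verified by property test to 1e-9) and give
`locomotory_rate ≥ speed` whenever any stopping occurs alongside movement.

## Box-counting fractal dimension

A 10-min window is rasterized onto an M × M boolean grid (M a power of 2,
default 256) with a single isotropic scale `s = (M−1)/max(width, height)`
anchored at the arena origin — stretching the non-square arena would
distort angles and bias the slope. Consecutive samples are joined by
Bresenham lines (default): at 0.25 s sampling and a few mm/s, raw sample
points are disconnected dots whose fine-scale box counts collapse, while
the underlying path is continuous. `--raster-mode points` disables the
interpolation for sensitivity checks. At M = 256 over a 60-mm arena the
finest box (δ = 2 px ≈ 0.47 mm) sits below the typical per-frame
displacement, leaving at least three informative scales.

Boxes are axis-aligned, origin-anchored, with the dyadic size schedule
δ ∈ {2, 4, …, M/2}; a box counts if it contains any occupied pixel
("≥ 1 pixel" is the standard box-counting rule). Nested dyadic grids make
N(δ) non-increasing in δ, which the counter asserts on every run. The
dimension is the least-squares slope of log N(δ) against log(1/δ).

Saturated scales — N(δ) = 1, or all (M/δ)² boxes occupied — carry no slope
information and are excluded before fitting. The filter relaxes stepwise
if it would leave fewer than three scales: saturated scales are re-admitted
first, then N = 1 scales. This keeps the topological limit cases well
defined — a surface-filling raster is saturated at *every* scale and its
unfiltered slope is exactly 2, a single point gives slope 0 — while a
series with fewer than three scales is still an error. Calibration on
analytic geometries: a diagonal line track fits D = 1.027, a full sweep
D = 2.000, a depth-7 Sierpinski raster D = 1.585 (= log 3 / log 2 to
machine precision, because the bitwise construction makes every dyadic box
count an exact power of 3).

## SOM pattern classification

Features are min–max scaled to [0, 1] per parameter; the training minima
and maxima are stored and re-used for every later query (a held-out vector
is never scaled by its own range). A constant parameter is an error.

The SOM is the canonical sequential Kohonen algorithm: squared Euclidean
distance selects the best-matching unit (argmin is invariant to the square
root, so none is taken; ties break to the lowest node index), and every
node moves toward the input weighted by a Gaussian neighborhood of lattice
distance to the winner. The printed update rule of the assay literature
omits the neighborhood factor while its prose describes neighbors being
updated; the Gaussian form is the standard reconciliation and is what this
package implements. Defaults: 8 × 8 rectangular lattice (64 codebook
vectors for ~2000 training segments, comfortably more than 6 clusters),
10 epochs, α linear 0.5 → 0.01, σ linear max(R,C)/2 → 0.5, weights
initialized from distinct data rows, presentation order a fresh seeded
permutation each epoch. Training is bit-for-bit reproducible for a fixed
seed. σ ends at 0.5 rather than 1: with σT = 1 the converged codebook keeps
chains of interpolating nodes between data clusters, and at a k = 6 Ward
cut those chains can claim a cluster of their own, forcing two genuine
patterns to merge; σT = 0.5 lets the codebook collapse onto the data in the
final epochs. Schedules are presentation-based (α and σ decay over the
total number of vector presentations).

The trained codebook is clustered by Ward's minimum-variance linkage
(`scipy.cluster.hierarchy`) and cut into k = 6 clusters; the merge tree is
retained and exportable as Newick for dendrogram inspection. Cluster
quality diagnostics: quantization error per epoch is recorded on the model
(non-increasing on average across seeds), and component planes (per-
parameter lattices of denormalized weights) are exportable.

Cluster naming replaces visual inspection with a deterministic
profile-ranking rule on the denormalized cluster-mean profiles:
P1 = highest speed (line), P6 = longest stop time (stay), P3 = highest
acceleration among the rest (cross), and the remaining three by decreasing
speed: P2 (loop), P4 (shaking), P5 (swirl). This ordering encodes the
qualitative profile descriptions of the six patterns; exact profile ties
raise an error requesting manual assignment rather than guessing.

## Paired statistics

Endpoints are per-subject summaries: mean of each movement parameter over
all 5-s segments, mean fractal dimension over all 10-min windows, and the
percentage of each pattern among the subject's classified segments
(pattern tests are per-subject percentages paired across subjects — with
10 animals this yields df = 9). The one-tailed direction of every endpoint
is declared a priori in configuration (speed, locomotory rate,
acceleration, fractal dimension, P1–P3: decrease after treatment; stops,
turning rate, meander, P4–P6: increase). No multiple-testing correction is
applied by default, matching common practice in this assay family; a
Bonferroni option exists. If two phases are literally identical the
difference vector is all-zero and the report shows t = 0, p = 0.5 (no
evidence) instead of failing; a *nonzero* constant difference still raises
the zero-variance error, since a t statistic is undefined there.

## Synthetic study generator

The generator emulates the assay's design — n subjects (default 10)
recorded individually for 24 h before and 24 h after treatment — because
raw tracking data for this assay type are not publicly deposited. Each
session is a chain of 5-s correlated-random-walk blocks with pose
continuity; block archetypes are drawn i.i.d. from the phase's pattern
composition and double as ground-truth labels (blocks align exactly with
the 5-s segmentation grid).

Default archetype kinematics (speed mean ± sd mm/s; turn rad/s; stop
fraction): line 9.0 ± 0.6 straight; loop 5.5 ± 0.6 with a constant-sign
3 rad/s turn; cross 5.0 ± 2.5 with zero-mean 4 rad/s heading noise (the
large speed variance gives it the highest acceleration); shaking 3.0 ± 0.4
with alternating-sign 6 rad/s turns; swirl 1.5 ± 0.3 with constant-sign
3 rad/s turns and a 15% stop bout; stay 0.2 ± 0.15 with an 80% stop bout
and mild heading drift. These values were chosen once so that (a) the six
archetypes are separable in the seven features (nearest-centroid recovery
> 95%, the stated prerequisite for SOM validation) and (b) phase-mean
speeds and turning rates land at the magnitudes reported for this assay
(~5 mm/s untreated, ~3.5 mm/s treated). Stay uses mild rather than random
heading drift because near-zero step distances make meander's variance
explode otherwise, smearing the stay cluster across feature space.

Phase compositions pin the two published percentages exactly (P1: 25.4%
before, 17.1% after; P6: 14.7% before, 22.5% after); the other four
patterns are implementer defaults (before: P2 0.240, P3 0.180, P4 0.096,
P5 0.084; after: P2 0.141, P3 0.101, P4 0.171, P5 0.192), obtained by
scaling plausible raw weights to fill the remaining probability mass so
the anchors are untouched. Per-subject compositional jitter (additive
Gaussian, sd 0.015, floored and renormalized) creates realistic
between-animal variance for the paired tests.

Walls reflect specularly at frame granularity: a step that would exit has
its offending velocity component flipped *before* moving, so every stored
step keeps its exact length and coordinates never leave the arena (steps
are capped at 45% of the smaller arena dimension per frame, making one
reflection sufficient away from corners; a corner fallback clamps). No
boundary-specific behavioral state is simulated.

What the generator does *not* emulate: tracking noise and dropouts,
identity switches, diel activity rhythms, gradual toxicokinetic onset
(phases are stationary), within-block behavioral transitions, and any 3-D
motion. Passing tests on synthetic sessions therefore validate the
*pipeline* — feature algebra, estimator calibration, classifier recovery,
statistical directionality — not biological realism of the tracks.

## Problem sizes used in validation

The test suite and the worked example run the study design at reduced
scale — 1-h sessions (720 blocks each) for 10 subjects, SOM training on
1000 randomly drawn segments per phase, fractal dimension on six 10-min
windows per session, and 100-replicate bands for the power and type-I
checks of the P1/P6 pattern tests. The generator's own default remains the
full 24-h session length.

## Known limitations

* The saturation-filter relaxation means very short or degenerate tracks
  return topological fallback slopes (0 or 2) rather than erroring; check
  `r_squared` and `n_fit_points` when screening real data.
* Pattern naming assumes the six-cluster structure of this assay; other
  taxa or stressor responses may need a different naming rule or manual
  assignment.
* The SOM is a plain sequential rectangular-lattice implementation; batch
  training, hexagonal/toroidal lattices and automatic cluster-count
  selection are deliberately absent.
* Fractal dimension is 2-D; depth information from stereo or volumetric
  tracking is not modelled.
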