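# daphmove

Movement-track analysis for behavioral ecotoxicology. `daphmove` takes 2-D
swimming trajectories of *Daphnia magna* (or any animal tracked at a fixed
frame rate in a rectangular arena) and quantifies how a chemical treatment
changes behavior, at two time scales:

* **Long windows (10 min)** — overall track complexity, summarized by the
  box-counting fractal dimension
  `D = slope of log N(δ) vs log(1/δ)`, where `N(δ)` is the number of grid
  boxes of side `δ` intersecting the rasterized track. `D ≈ 1` for smooth,
  linear swimming; `D ≈ 2` for tracks that fill the arena evenly.
* **Short windows (5 s)** — instantaneous movement patterns. Each segment is
  described by seven parameters (speed, acceleration, locomotory rate, stop
  number, stop time, turning rate, meander) and classified into one of six
  canonical patterns — P1 line, P2 loop, P3 cross, P4 shaking, P5 swirl, P6
  stay — by a sequential Kohonen self-organizing map (SOM) whose codebook is
  cut into six clusters with Ward's linkage:

  ```
  d_j(t) = Σ_i (x_i − w_ij(t))²                     (winner = argmin_j d_j)
  w_ij(t+1) = w_ij(t) + α(t) h_cj(t) (x_i − w_ij(t))  (Gaussian neighborhood h)
  ```

Before/after treatment contrasts (per-subject parameter means, mean fractal
dimension, pattern percentages) are tested with one-tailed paired-sample
t-tests, `t = mean(d) / (sd(d)/√n)`, `df = n − 1`.

Because the original video-tracking recordings of this kind of assay are
rarely published, the package ships a seeded synthetic generator
(`daphmove.synthetic`): a correlated random walk with six movement
archetypes, chained into 5-s blocks with a prescribed pattern composition
and specular wall reflection. Generated sessions carry ground-truth block
labels, so the whole pipeline can be validated end to end.

## Worked example

Ten synthetic subjects, one hour of recording per phase, full pipeline:

```python
import pandas as pd
import daphmove as dm
from daphmove import analysis, som
from daphmove.features import build_feature_matrix

before, after = dm.default_study(seed=42, duration_s=3600.0)

def features(tracks):
    segs = [s for tr in tracks for s in dm.segment_track(tr, window_s=5.0)]
    return build_feature_matrix(segs)

fb, fa = features(before), features(after)

train = pd.concat([fb.sample(1000, random_state=0),
                   fa.sample(1000, random_state=1)], ignore_index=True)
model = som.train_on_features(train, rows=8, cols=8, epochs=10, seed=7)
clusters = som.name_patterns(model, som.ward_cluster(model, k=6))

def labels(feats):
    out = feats[["subject_id", "phase", "segment"]].copy()
    out["pattern"] = som.classify_segments(model, clusters, feats)
    return out

def fractal(tracks):
    return pd.DataFrame(
        {"subject_id": tr.subject_id, "D": r.D}
        for tr in tracks
        for r in dm.track_fractal_dimension(tr, window_s=600.0, M=256)
    )

report = analysis.compare_phases(fb, fa, fractal(before), fractal(after),
                                 labels(fb), labels(fa))
print(analysis.summary_text(report))
```

Output:

```
Paired comparison over 10 subjects (alpha=0.01)
endpoint                  before       after        t  df         p  sig
speed                      4.862       3.556    22.30   9  1.73e-09  *
acceleration               3.738       2.817    14.26   9  8.74e-08  *
locomotory_rate            4.920       3.613    22.56   9  1.56e-09  *
stop_number                0.578       0.814   -12.32   9  3.07e-07  *
stop_time                  0.915       1.397   -10.09   9  1.66e-06  *
turning_rate               2.180       2.376    -4.37   9  8.97e-04  *
meander                    0.847       1.231   -22.84   9  1.41e-09  *
fractal_dimension          1.597       1.525    20.95   9  3.01e-09  *
P1                        25.111      16.306     9.74   9  2.23e-06  *
P2                        29.681      18.417    16.11   9  3.03e-08  *
P3                        11.597       6.375    10.96   9  8.27e-07  *
P4                         9.833      17.000   -15.48   9  4.30e-08  *
P5                         8.569      18.917    -8.87   9  4.81e-06  *
P6                        15.208      22.986    -6.76   9  4.13e-05  *
Pattern composition (% of segments):
  before P1= 25.1  P2= 29.7  P3= 11.6  P4=  9.8  P5=  8.6  P6= 15.2
  after  P1= 16.3  P2= 18.4  P3=  6.4  P4= 17.0  P5= 18.9  P6= 23.0
```

Reading it: treated animals swim slower (speed 4.86 → 3.56 mm/s), turn more
per unit time and distance, pause more, and their tracks lose spatial
complexity (mean 10-min fractal dimension 1.60 → 1.53). The pattern
composition shifts away from active shapes (linear P1 falls 25.1% → 16.3%)
toward inactive ones (stay P6 rises 15.2% → 23.0%); every endpoint's paired
t-test (df = 9) rejects at α = 0.01 in its pre-declared direction.

The same pipeline is available from the shell via the `daphmove` command
(`simulate`, `features`, `fractal`, `train-som`, `classify`, `report`); see
`daphmove --help`.

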