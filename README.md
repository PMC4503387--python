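# mpquant

Quantitative analysis of micropatterned stem-cell colonies: single-cell
migration, radial spatial patterning, and the contraction of beating
cardiac tissue.

When pluripotent stem cells are confined to circular adhesive islands and
pushed through mesoderm induction, the colony self-organises radially:
cells condense into a high-density, marker-positive annulus at the pattern
perimeter, migration becomes directionally biased, and — on patterns that
go on to form three-dimensional cardiac microchambers — the centre starts
beating. `mpquant` is the analysis layer for such experiments. It is
written for experimentalists who already have single-cell track tables,
nucleus tables (from any segmentation tool), or time-lapse videos of
beating tissue, and want the standard quantities with tested numerics:

* **Migration** (`mpquant.tracks`) — mean-square displacement by the
  overlapping-interval method; persistent-random-walk (PRW) fits
  `MSD(t) = 2S²P[t − P(1 − e^(−t/P))]` returning persistence time *P*,
  speed *S* and motility coefficient *μ = S²P/2*; "biased" vs "random"
  classification (*μ* > 5 μm²/min with an explicit goodness-of-fit gate);
  centre/perimeter cohort summaries with t-tests.
* **Spatial patterning** (`mpquant.spatial`) — 15-μm annulus density
  heatmaps, marker-positive fractions (OCT4+, EdU+, …), nucleus shape
  index, perimeter/centre density ratio, and two-term power fits
  `y = a·x^b + c` of intensity vs colony thickness with 95% CIs, SSE,
  RMSE and R².
* **Contraction** (`mpquant.contraction`) — block-matching motion
  estimation on 20-fps videos, motion waveforms, beat frequency and
  maximal contraction velocity, contraction heatmaps, and control-vs-drug
  group comparisons.
* **Synthetic ground truth** (`mpquant.synthetic`) — generators for PRW
  tracks (exact Ornstein–Uhlenbeck discretisation), radially structured
  colonies, and beating-tissue videos with known displacement fields;
  every estimator above is validated against them.

Fitting follows the Model/Results idiom: `PRWModel(...).fit()` and
`PowerProfileModel(...).fit()` return results objects with `summary()`,
`conf_int()` and `predict()`.

## Worked example

Simulate a 400-μm pattern whose centre cells migrate fast and
persistently (P = 120 min, S = 0.6 μm/min) while perimeter cells do not
(P = 30 min, S = 0.3 μm/min), then summarise by region:

```python
import math
import numpy as np
from mpquant import (PRWModel, RegionRule, assign_region,
                     classify_migration, summarize_cohort, synthetic as syn)

rng = np.random.default_rng(0)
tracks, fits = [], []
for i in range(50):
    centre = i % 2 == 0
    P, S = (120.0, 0.6) if centre else (30.0, 0.3)
    r0 = rng.uniform(0, 80) if centre else rng.uniform(120, 190)
    th = rng.uniform(0, 2 * math.pi)
    cfg = syn.SyntheticTrackConfig(P, S, origin=(r0 * math.cos(th),
                                                 r0 * math.sin(th)),
                                   seed=100 + i)
    tr = assign_region(syn.simulate_prw_track(cfg, cell_id=i), RegionRule())
    tracks.append(tr)
    fits.append(classify_migration(PRWModel.from_track(tr).fit()))
print(summarize_cohort(tracks, fits).by_region.round(3))
```

```
              n  pct_biased  velocity_mean  velocity_sd  motility_coefficient_mean  ...
centre     25.0       100.0          0.540        0.072                     30.152  ...
perimeter  25.0         0.0          0.225        0.024                      1.171  ...
```

All 25 centre cells are classified "biased" and none of the perimeter
cells are; centre velocity (0.54 μm/min) and motility dominate, as built
into the simulation. Note the large per-cell spread of fitted *μ* and *P*
(s.d. comparable to the mean): single 24-h tracks carry little information
about *P*, which is why parameter recovery is guaranteed for ensembles,
not single cells. An ensemble fit over 200 tracks simulated at P = 60,
S = 0.5:

```python
cfgs = [syn.SyntheticTrackConfig(60.0, 0.5, seed=i) for i in range(200)]
print(PRWModel.from_tracks(syn.simulate_track_cohort(cfgs)).fit().summary())
```

```
Persistent Random Walk fit
============================================
n lags:               16
P (persistence, min): 60.04
S (speed, um/min):    0.4965
mu (um^2/min):        7.401
relative residual:    0.004975
```

recovers P within 0.1% and μ = 7.40 vs the true 7.5. The spatial and
contraction layers work the same way:

```python
from mpquant import (PatternGeometry, annulus_density_map,
                     spatial_density_ratio, block_match_motion,
                     motion_waveform, detect_beats)

nuc = syn.simulate_colony(syn.SyntheticColonyConfig(seed=2, n_cells=4000))
dmap = annulus_density_map(nuc, PatternGeometry())
print(spatial_density_ratio(dmap, RegionRule()))   # 2.102 (3x band -> ~2.2)

beat = syn.simulate_beating_stack(
    syn.SyntheticBeatConfig(beat_frequency=1.0, peak_velocity=10.0, seed=3))
wf = detect_beats(motion_waveform(
    block_match_motion(beat.stack, 16, 4, 8)))
print(wf.beat_frequency, wf.max_contraction_velocity)
# 1.000 Hz, 9.48 um/s against a configured 10 um/s peak
```

A command-line interface mirrors the library:

```bash
mpq synth colony --seed 1 --out nuclei.csv
mpq spatial density --in nuclei.csv --out density.csv --png density.png
mpq beat analyze --stack stack.tif --fps 20 --pixel-size 0.65 --out-prefix run1
mpq run --config config.yaml --tracks t.csv --nuclei n.csv --out report.json
```

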