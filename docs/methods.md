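# Methods

`mpquant` quantifies three observables of geometrically confined stem-cell
colonies: single-cell migration on a circular micropattern, the radial
organisation of nuclei and markers across the colony, and the contraction
of beating tissue recorded on video. This note documents the models, the
estimators, the synthetic generators the tests run against, and the
numerical choices that were genuinely open.

## Persistent random walk migration

A migrating cell is modelled as a persistent random walk (PRW): its
velocity decorrelates over a persistence time *P* (minutes) while its
root-mean-square speed is *S* (μm/min). The two-dimensional mean-square
displacement is

    MSD(t) = 2 S² P [ t − P (1 − e^(−t/P)) ],

ballistic (*S²t²*) for *t ≪ P* and diffusive (*4μt*) for *t ≫ P*, with the
random-motility coefficient *μ = S²P/n_d* (*n_d = 2* for migration on a
substrate). Tracks are sampled every Δt = 30 min for 49 frames (24 h) by
default.

**MSD estimator.** The overlapping time-interval method: lag *k* on a track
of *N+1* positions averages all *N−k+1* squared displacements between
positions *i* and *i+k*. Fits use lags up to one third of the track
duration, where the estimator variance is still moderate.

**Fitting.** `PRWModel.fit()` runs nonlinear weighted least squares over
(log P, log S) — the log transform enforces positivity without bounds —
from several starting points (ballistic- and diffusive-motivated), keeping
the best. Single curves are weighted by √n_pairs per lag. For replicate
ensembles (`PRWModel.from_ensemble`, used by `from_tracks`), the fit is
generalised least squares on the ensemble-mean curve, whitened by the
empirical covariance of that mean estimated across the replicate per-track
curves and shrunk 10% toward its diagonal for conditioning. MSD values at
neighbouring lags are strongly correlated and their standard deviation
grows with the MSD itself, so GLS roughly halves the spread of recovered
*P* and *μ* relative to per-lag weighting (≈3–4% s.d. at 200 tracks per
condition, close to the information limit of curve-based fitting on this
window).

**Degenerate and ridge cases.** A zero MSD (stationary cell) is reported
as *S = 0*, *μ = 0*, residual 0, with the persistence time set to the
first lag purely so the identity *μ = S²P/2* stays exact; the result is
flagged `degenerate`. In the diffusive limit only the product *S²P* is
identified; the optimizer may exhaust its step budget wandering that flat
ridge with an essentially perfect fit, so a relative residual below 1e−6
also counts as convergence.

**Classification.** A cell is "biased" when the fit converged, the
relative residual ‖r‖/‖msd‖ is at most `gof_threshold` (default 0.3,
configurable — the field reports only that a track "fits" the model, so
the statistic must be explicit) and *μ* strictly exceeds `mu_threshold`
(default 5 μm²/min). Ties lose: *μ* exactly 5 is "random". Likewise the
centre/perimeter partition uses the strict rule: a cell whose *first*
position lies more than 100 μm from the centre of the 400-μm pattern is a
perimeter cell; exactly 100 μm is centre.

**Cohort summaries** report per-region mean ± s.d. of migratory velocity
(mean frame-to-frame displacement / Δt), *μ*, *P* and the percentage of
biased cells, with two-sided Student's t-tests between regions (a generic
utility, not a contribution of this package).

## Synthetic tracks

The generator draws an exact discretisation of the Ornstein–Uhlenbeck
velocity process with correlation time *P* and per-component stationary
variance *S²/2*: at each step the next velocity and the *integrated*
displacement over the interval are drawn from their exact joint Gaussian
law. The ensemble MSD therefore equals the PRW closed form at every lag
and sampling interval, not only as Δt → 0 — which is what makes the
parameter-recovery tests meaningful. Velocity starts in its stationary
distribution, so individual tracks have random initial speeds; in the
ballistic limit (*P ≥ 100× duration*) the closed form is within 1% of
*S²t²*, while a single unlucky slow track can still wander visibly
relative to its own small speed.

## Spatial patterning statistics

Nuclei enter as a table of centroids (μm, pattern centre at the origin),
axis lengths, and boolean marker flags. Thresholding raw channel
intensities into flags is upstream of this package (an Otsu utility is
provided only for the synthetic raster path).

* **Annulus density map** — concentric 15-μm annuli, half-open
  [inner, outer) with the terminal annulus truncated at the pattern radius
  and closed there (a rim nucleus still counts). The boundary convention is
  arbitrary but fixed and tested. Densities are counts per true annulus
  area; counts are also reported because density and count heatmaps answer
  different questions. Out-of-pattern nuclei are excluded but tallied, so
  counts always conserve.
* **Marker-positive fraction** — positive/total counts, overall and per
  centre/perimeter region, reusing the migration region rule (threshold
  100 μm by default) for internal consistency.
* **Nucleus shape index** — longest/shortest axis (≥ 1; 1 is a circle).
  Records with non-positive axes are rejected with a reason rather than
  silently dropped.
* **Spatial density ratio** — pooled perimeter density / pooled centre
  density, the regions split at the radial threshold; an annulus straddling
  the threshold goes to the side containing its midpoint. An empty
  perimeter returns 0 and an empty centre returns ∞ (flags, not
  exceptions).
* **Power profile fit** — y = a·x^b + c by nonlinear least squares from
  several exponent starting points, reporting 95% t-based confidence
  intervals, SSE, RMSE (√(SSE/(n−3))) and R². A numerically constant
  profile is unidentifiable in (a, b): it is flagged, with a = 0,
  c = mean(y) and R² = 0. A fit whose exponent CI spans zero is flagged
  the same way rather than reported silently.

## Synthetic colonies

Nuclei are point-plus-ellipse records (rendering to label images is an
optional raster path used by the round-trip test). Positions are sampled
uniformly by area except inside a configurable annular band whose density
is multiplied (default 3× over 150–200 μm of a 400-μm pattern), emulating
the condensation ring at the colony perimeter; marker positivity (default
0.9 in the band, 0.1 elsewhere) and nucleus elongation (axis ratios 2.0
band / 1.2 elsewhere, band nuclei tangentially oriented) follow the band
membership. The nucleus minor axis is ~6 μm with small lognormal jitter. A
packing bound of 4 μm² minimum area per nucleus rejects absurd counts.
What the generator does **not** emulate: nucleus overlap and exclusion
areas, marker intensity gradients within a region, segmentation errors —
so passing tests show the estimators are correct on clean tables, not that
upstream segmentation of real micrographs would be.

## Contraction analysis

**Block matching.** For each consecutive frame pair, each block (16 px, on
an 8-px grid) takes the integer displacement minimising the sum of
absolute differences within ±8 px (defaults; tests use ±4 where the
synthetic motion is sub-pixel). Sub-pixel refinement fits a 1-D parabola
along each axis through the *squared*-difference cost at the minimum and
its neighbours: the SSD cost of smooth texture is quadratic in the shift
mismatch, whereas the SAD valley is V-shaped and a parabola on it
underestimates offsets by up to ~35% at quarter-pixel shifts. A block is
confident when its intensity s.d. is at least `min_std` (default 5
intensity units) and its cost minimum is unique; low-confidence blocks
carry zero vectors and are excluded from waveforms and heatmaps.
Remaining known biases: direction-dependent magnitude error of a few
percent on warped (non-rigid) texture, and over-reading by blocks that
straddle the moving-tissue rim, where moving and static content mix — the
heatmap linearity property therefore holds on interior blocks.

**Waveform and beats.** The motion waveform is the spatial mean speed over
confident blocks, timestamped at frame-pair midpoints. A beating tissue
shows two speed humps per cycle (contraction, then relaxation). Peaks are
detected by prominence (default 25% of the waveform range), separated by
at least 0.1 s, and above an absolute floor of 1 μm/s that rejects the
sub-pixel jitter of quiescent tissue. Alternate peaks are assigned to the
contraction phase starting from the larger of the first two; when the
first two differ by less than 10% the first is taken — real contraction
peaks exceed relaxation peaks by far more than that, while for a
symmetric synthetic beat only measurement bias separates the humps and
phase order (contraction first) is the honest tie-break. Beat frequency is
(number of contraction peaks − 1) / (time between first and last); a
peak-interval estimator is more robust than an FFT on 25-s records with
few beats, and the FFT serves as a cross-check in tests. Maximal
contraction velocity is the largest contraction-peak speed.

**Group comparison** tabulates beat frequency, maximal contraction
velocity and any externally measured chamber metrics for two groups with
two-sided t-tests; zero-variance comparisons report exact equality (p = 1
when the groups coincide) instead of NaN.

## Synthetic beating tissue

A band-limited noise texture (Gaussian-smoothed white noise, σ = 2 px,
which gives block matching structure to lock onto) fills a disc covering
~84% of the frame width. Every texture point moves radially with the
common displacement δ(t) = A·sin(2πft), A = peak_velocity/(2πf), tapered
to zero inside a 5-px core where the radial direction is undefined; frames
are bilinear resamplings of the base image along the analytic inverse map,
plus Gaussian pixel noise. Because the displacement magnitude is uniform
over the disc, the spatial-mean waveform of the moving tissue equals
|dδ/dt| and the configured peak velocity is directly recoverable. The
exact per-frame displacement is returned alongside the stack as the oracle
for the motion estimator. Defaults (20 frames/s, 500 frames, 64-px frames
at 0.5 μm/px, noise s.d. 1 against a texture s.d. of 60) keep a full
four-stack frequency sweep within seconds while the peak frame-to-frame
motion stays near one pixel, the regime the sub-pixel refinement is
designed for.

## Pipeline and configuration

A single YAML config with per-stage sections validates every field at load
time and reports all violations at once. `run_pipeline` executes the
enabled stages (tracks → spatial → contraction) over CSV/TIFF inputs,
isolates stage failures, and emits one JSON report with provenance (config
hash, seed, package version, no timestamps) that is byte-identical across
repeated runs. All randomness flows from explicit seeds.

## Problem sizes

The test suite and `scripts/acceptance.py` use 200 tracks per migration
condition (49 frames each), colonies of 4,000–10,000 nuclei, and 100—500
frame videos at 64 px — sizes chosen so every statistic sits well inside
its sampling-error budget while a full run of the suite completes in a few
minutes on one CPU.

## Known limitations

* Single-track PRW fits are intrinsically noisy at 49 frames; per-cell
  classifications are threshold calls on noisy fits, which is why the
  recovery guarantees are stated for ensembles.
* The block matcher assumes locally rigid translation; rotation, shear and
  out-of-plane motion are unmodelled, and tissue-boundary blocks can
  over-read.
* The beat-phase labels (contraction vs relaxation) rely on amplitude
  asymmetry; for a perfectly symmetric waveform the phase assignment is a
  convention.
* No image segmentation: nucleus tables are inputs, produced upstream or
  by the synthetic raster utilities.
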