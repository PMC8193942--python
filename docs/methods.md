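# Methods

## Data model and trial standardization

A trial is a uniformly sampled binocular recording: timestamps, left/right
gaze positions, left/right pupil diameters and a validity flag per sample.
Gaze positions are carried in degrees of visual angle internally; a
pixel-unit source must declare `pixels_per_degree` so the 1° dispersion
threshold keeps its meaning. All trials of a dataset are standardized to
one length by keeping the first `floor(length × rate)` samples — trials are
cut, never padded, so classifiers cannot exploit trial length. The CSV
interchange format (one row per sample; `trial_id, participant_id, task_id,
condition, t, lx, ly, rx, ry, lp, rp, valid`) round-trips bit-exactly.

## Oculomotor event detection

**Blinks** are maximal runs of invalid samples lasting at least
`blink_min_duration_ms` (default 50 ms). Shorter invalid runs are treated
as tracker dropouts and linearly interpolated (`interpolate_gaps_below_ms`,
default 50 ms).

**Fixations** use dispersion-threshold identification (I-DT) on the
two-eye average stream with blink samples removed: grow a window of at
least `fixation_min_duration_ms` (default 100 ms; the threshold literature
gives no unique value, this is the common default) while the Manhattan
dispersion `(max x − min x) + (max y − min y)` stays within
`dispersion_threshold_deg` (default 1°). Each emitted fixation's member
samples satisfy the dispersion bound by construction. The sweep never
crosses a blink, so fixations and blinks cannot overlap.

A documented post-step (`merge_adjacent_fixations`, used by
`detect_events`) re-joins fixations the greedy window split apart: the
sweep can anchor its first window on trailing saccade-ramp samples, spend
the dispersion budget on them, and cut a true fixation in two. Split
pieces are adjacent in time (≤ 100 ms, one minimum window) and essentially
in the same place (≤ 0.5°), whereas genuinely distinct fixations are
separated by a saccade — tens of milliseconds *and* degrees. The raw I-DT
output remains available via `detect_fixations_idt`.

**Saccades** fill inter-fixation gaps not occupied by a blink (a blink
covering at least half the gap suppresses the saccade — the eyes were
closed, not in flight). Amplitude is the Euclidean distance between the
flanking centroids; peak velocity comes from a central-difference velocity
estimate.

## The 76-feature summary vector

Six families, fixed order, schema frozen in `features.FEATURE_NAMES`
(exactly 76 unique names — the single source of truth):

| family | count | content |
|---|---|---|
| fixation | 9 | count + 8 duration statistics |
| saccade | 20 | count, 8 duration stats, 8 amplitude stats, inter-saccade angle mean/sd, fixation:saccade time ratio |
| blink | 9 | count + 8 duration statistics |
| pupil | 5 | mean/sd/median/min/max of the two-eye mean diameter |
| vergence | 23 | 8 stats of v(t) = left_x − right_x overall, 8 during fixations, 7 of successive absolute pair differences |
| spatial | 10 | minimal-enclosing-circle radius, scanpath length, 8 gaze-speed statistics |

The 8 distribution statistics are mean, sd, median, min, max, range,
kurtosis, skewness — population (biased) definitions, kurtosis as excess
kurtosis, to pin down cross-implementation drift. Undefined statistics over
empty event sets are 0; the count feature carries the emptiness
information. Distance-dependent vergence features that would need screen or
inter-pupillary geometry are deliberately absent. The pair-based vergence
family carries 7 statistics (no kurtosis) so the schema totals exactly 76.

The minimal enclosing circle is Welzl's randomized algorithm (seeded
shuffle, exact up to ~1e-10 tolerance); tests verify it against an O(n⁴)
oracle over all pair- and triple-defined candidate circles.

Normalization is z-scoring with means/sds estimated on training data only
(population sd; zero-variance features map to 0). Ranking uses the one-way
ANOVA F statistic or a k-nearest-neighbour mutual-information estimate
(k = 3, seeded); undefined scores become 0 and ties break by schema order.
Model selection evaluates all 14 (estimator, k) combinations,
k ∈ {10, …, 70}, on identical stratified five-fold splits with ranking and
scaling re-fitted inside every training fold.

## Imaging time series

Each of the four raw coordinate channels (left/right × x/y) is
blink-filtered (samples inside blink windows deleted, order preserved) and
encoded three ways:

* **GASF/GADF** — the series is reduced to the image side `s` (default 48)
  by piecewise aggregate approximation (PAA; weighted fractional-boundary
  segments, exact segment means when lengths divide), rescaled to [−1, 1]
  (constant series → zeros), then `G_ij = cos(φ_i + φ_j)` or
  `sin(φ_i − φ_j)` with `φ = arccos x̃` — computed in the closed forms that
  avoid explicit angles; arccos inputs are clipped to absorb ±1e-12
  excursions.
* **MTF** — quantile bins (default Q = 8; edges at empirical quantiles,
  ties to the lower bin, duplicate edges collapse with a warning), a
  row-stochastic first-order transition matrix W (empty rows uniform), and
  `M_ij = W[bin_i, bin_j]` on the *full* filtered series. The field is then
  blurred to s × s by non-overlapping patch averaging, computed without
  materializing the n × n matrix via the bin-membership aggregation
  `(A B) W (A B)ᵀ` (A = PAA weight matrix, B = bin one-hot), which equals
  the explicit patch mean exactly. A `paa-series` switch reduces the series
  before the MTF instead, matching common reference tooling.

Each image is min–max normalized to [−1, 1] independently (constant →
zeros). A trial yields 12 images exposed both as the 3 × 4 tiled matrix
(rows MTF/GASF/GADF, columns left_x/left_y/right_x/right_y) and as the
12-channel stack the CNNs consume. A gaze heatmap (occupancy histogram,
mass-normalized then min–max scaled) provides the spatial-information
baseline.

The stacked 12-channel input (rather than the single-channel tiling) is
the default CNN input because the AlexNet parameter count is consistent
only with a 12-channel first convolution; the tiled rendering is kept for
visualization and as an alternative input.

## CNN architectures and training

**SimpleNet** (default input 12 × 48 × 48): conv 5×5 → 32 channels, ReLU,
max-pool 2×2, conv 5×5 → 32, ReLU, max-pool 2×2, flatten (2592), FC 512,
ReLU, dropout, FC 4 (linear projection — a ReLU on a 4-unit bottleneck
dies permanently under He initialization at small data scale), output 2.
Total learnable parameters: 1,364,942. Valid padding; below 16 px input
the convolutions pad to stay defined.

**AlexNet**: the classical 5-conv / 3-max-pool / 3-FC layout with adaptive
6×6 average pooling before the classifier, adapted to 12 input channels
and 2 outputs, trained from scratch: 57,081,730 parameters (≈ 42 ×
SimpleNet). Inputs must be at least 63 px per side (upscale panels).

Both run on a small numpy layer library (im2col convolution, exact
backprop verified against finite differences) with softmax cross-entropy
and Adam (optional decoupled weight decay). Defaults: 50 epochs, batch 32,
learning rate 1e-4, dropout 0.5 — all overridable; training is
bit-reproducible per seed. CPU-only is the supported path.

## Evaluation protocols and statistics

Split plans are deterministic per seed and reused across classifiers so
accuracies are paired. Person-dependent: per-participant stratified
five-fold; the comparison unit is the per-participant mean fold accuracy.
Person-independent: participants are shuffled and partitioned into five
disjoint groups. Leave-one-task-out: one fold per task. Folds whose
training labels collapse to one class are skipped and recorded, never
imputed.

The paired comparison is a one-tailed Wilcoxon signed-rank test (row
better than column), zero differences dropped (all-zero → p = 1), exact
null distribution up to n = 25 pairs via a dynamic program over doubled
midranks (agrees with full 2ⁿ enumeration, ties included), tie-corrected
normal approximation with continuity correction above. Rendered tables
round p to 3 decimals (so 0 and 1 are possible); raw values are retained
in the JSON artifact.

## Synthetic gaze generator

Trials are alternating fixations (centroid + Gaussian jitter sd 0.08° +
linear drift 0.3°/s in a random direction) and minimum-jerk saccade ramps
(20–80 ms, amplitude gamma with mean 4°, floor 2° — microsaccades are out
of scope), with blinks (Poisson count at 10/min; log-normal durations,
mean 180 ms, floor 80 ms) inserted between fixations as invalid runs
followed by a landing jump, so planted fixations never straddle a blink.
Binocular structure is a horizontal vergence process (participant-level
offset ~1° + AR(1) noise, sd 0.15°) split symmetrically between the eyes;
pupil is baseline 3.5 + slow AR(1) noise; measurement noise 0.02° per eye
channel. Fixation durations are log-normal (mean 260 ms, sd 90 ms,
truncated at 150 ms so every planted fixation stays detectable at the
100 ms/1° settings); the final fixation extends to the trial end. The
values are plausible for screen-based task viewing with a stabilized head;
they are a study-condition choice, not fits to any dataset.

The scanpath itself is condition-bearing: condition A follows a serpentine
grid scan (5 × 4 cells, 2.5° steps, 0.3° landing jitter — stimulus-driven
viewing of a structured task display), while condition B replaces grid
steps with a random-walk jump with probability
`clip(effect_size × delta_scan_disorder, 0, 1)` per saccade
(internally-directed gaze decoupled from the stimulus). On top of that,
condition B's parameter means shift multiplicatively with `effect_size`:
longer fixations (+25 %/unit), smaller saccade amplitudes (−10 %),
more blinks (+25 %), larger vergence variability (+30 %), larger pupil
(+3 %). The shift directions are illustrative of internal-vs-external
attention reports; they are not a measured physiology, and passing tests
on this generator shows pipeline correctness and statistical calibration,
not real-data performance. `effect_size = 0` yields exactly identical
generative laws for both conditions. Per-participant log-normal random
effects (sd 0.10) on all means make person-dependent and
person-independent evaluation genuinely different. One master seed spawns
per-participant and per-trial child streams by fixed arithmetic, so any
subset is reproducible.

What the generator does **not** emulate: saccadic main-sequence curvature
and overshoot, pupil light reflexes, smooth pursuit, microsaccades,
calibration drift, or realistic tracker noise spectra.

## Problem sizes used by the shipped checks

Transform and geometry oracles run on 500/1,000 random small instances;
event recovery on 200 trials at 250 Hz/10 s; the calibration/power study
on 10 participants × 40 trials at 60 Hz/5 s with 24 px panels and
SimpleNet trained 10 epochs (batch 4, learning rate 1e-3, dropout 0.5) —
sizes chosen so the full suite runs in minutes on one CPU while keeping
≥ 400 predictions per calibration check. Null calibration uses a
two-sided binomial test at α = 0.01 per classifier; planted-effect power
requires both pipelines to exceed 0.6 mean person-dependent accuracy at
`effect_size = 2`.

## Known limitations

* Fixation detection quality degrades for jitter above ~0.15° at the 1°
  Manhattan threshold; the I-DT window can also absorb saccade-ramp tails
  (mitigated, not eliminated, by the merge post-step).
* The MTF quantile count Q and the PAA-before-or-after-GAF order are
  conventions, exposed as configuration rather than fixed facts.
* AlexNet training at full size is computationally heavy on numpy; it is
  provided for architecture census, forward inference and small-scale
  training.
* Wilcoxon zero-difference handling (drop) and the person-dependent
  comparison unit (per-participant mean) are conventions, configurable at
  the call sites.
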