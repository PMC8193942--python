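# gazeits

Classifying binary attentional states (for example internally vs externally
directed attention) from binocular eye-tracking recordings, two ways:

1. **Statistical summary pipeline** — detect oculomotor events (blinks from
   invalid-sample runs at a 50 ms threshold; fixations with the I-DT
   dispersion algorithm at a 1° threshold; saccades from inter-fixation
   gaps), summarize each trial as a fixed 76-feature vector (fixation,
   saccade, blink, pupil, vergence and spatial-dispersion statistics),
   z-score, rank features by ANOVA F or k-NN mutual information, and
   classify with seven standard algorithms (NB, LogReg, RF, kNN, linSVM,
   MLP, AdaBoost).
2. **Imaging-time-series (ITS) pipeline** — encode each gaze coordinate
   series as images: the Gramian angular summation/difference fields
   ``GASF_ij = cos(φ_i + φ_j)``, ``GADF_ij = sin(φ_i − φ_j)`` with
   ``φ = arccos x̃`` of the [−1, 1]-rescaled series, and the Markov
   transition field ``MTF_ij = W[q_i, q_j]`` of quantile-bin transition
   probabilities. The 3 transforms × {left, right} × {x, y} = 12 images
   per trial (48 × 48 each, 3 × 4 tiled) feed a small CNN (**SimpleNet**,
   1,364,942 parameters) or an **AlexNet** adapted to 12 input channels
   (57,081,730 parameters).

Both pipelines are compared under three cross-validation protocols —
person-dependent, person-independent (group five-fold; no test participant
ever in training) and leave-one-task-out — with paired one-tailed Wilcoxon
signed-rank tests at α = 0.05 on identical splits.

Because comparable public datasets are scarce, the package ships a
synthetic binocular gaze generator that plants fixation/saccade/blink
structure, vergence and pupil dynamics at the studied recording regimes
(250 Hz/10 s, 120 Hz/15 s, 120 Hz/20 s), with a tunable between-condition
effect including an exact null (`effect_size=0`).

## Worked example

```python
import gazeits as g

cfg = g.preset("align_like", n_participants=5, trials_per_participant=8,
               effect_size=2.0, seed=3)
ds = g.generate_dataset(cfg)

trial = ds.trials[0]
ev = g.detect_events(trial)
print(len(ev.fixations), len(ev.saccades), len(ev.blinks))
# 52 49 2   -> events found in one 15-s trial

fv = g.extract_features(trial, ev)
print(len(fv.values), round(fv["fix_count"], 1), round(fv["verg_mean"], 2))
# 76 52.0 0.97   -> the 76-feature vector; vergence offset ~1 degree

panel = g.build_image_panel(trial, ev.blinks)
print(panel.stack().shape, panel.tiled().shape)
# (12, 48, 48) (144, 192)  -> 12 images tiled 3 rows x 4 columns

model = g.build_simplenet()
print(model.n_params)
# 1364942   -> SimpleNet learnable-parameter census
```

The numbers mean: the detector recovered the planted oculomotor events of
the trial; the summary vector always has exactly 76 named entries; the ITS
encoding always yields the 12-image panel; and the small CNN has exactly
1,364,942 learnable parameters.

An end-to-end comparison (simulate → events → features/panels → classify →
paired Wilcoxon report):

```bash
gazeits run --pipeline summary --protocol person_independent \
    --preset align_like --participants 8 --trials-per-participant 20 \
    --effect-size 2 --fixed-selection anova:30 --seed 7 --out-dir out/
```

which prints a Markdown table of mean accuracies and the pairwise p-value
matrix, and writes `report.json`, `splits.csv` and the resolved config for
provenance. See `examples/` for one short script per capability.

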