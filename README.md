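# fetalmotion

Detecting fetal movement from wearable inertial sensors, end to end and
reproducibly.

Reduced fetal movement is a clinical warning sign, but today it is assessed
by subjective maternal perception or by snapshot tests in a clinic.  A
promising alternative instruments the maternal abdomen with tri-axial IMUs:
during maternal movement the torso rotates approximately as a rigid body, so
four abdominal sensors and a chest reference see the same angular rate —
while a fetal movement deforms the abdominal wall locally and breaks that
agreement.  `fetalmotion` implements a full comparative pipeline around this
idea for researchers in wearable-sensor fetal monitoring:

- a **synthetic cohort generator** (five 128 Hz IMUs, shared rigid-body
  maternal motion plus gravity, localized band-limited fetal bursts,
  imperfect button-press perception, and a static+hip-hinge calibration
  segment), so every stage is testable without access to participant data;
- **preprocessing**: 1–20 Hz zero-phase Butterworth filtering and functional
  alignment of gyroscope axes from the calibration movements (x = gravity,
  y = frontal axis from the hip hinges, z = sagittal); acceleration axes are
  deliberately left unaligned;
- **labeling**: each button press at time *t* defines an event interval
  [*t*−3.5 s, *t*+1.5 s]; a window is positive iff its overlap with the
  union of event intervals exceeds 10% of the window length; training sets
  are rebalanced by discarding two-thirds of negatives (≈1:3 ratio);
- three **data representations** — 75 hand-engineered features per modality,
  raw 0.5 s time-series tensors, and 8 s STFT magnitude spectrograms
  (Hanning-16, stride 1 → 9×1009 per channel);
- three **classifiers** — random forest (scikit-learn, random-search tuned
  on validation F1), and numpy implementations with hand-written
  backpropagation of a 64-unit BiLSTM and a two-layer CNN;
- **evaluation**: trial-level Monte Carlo cross-validation with pre-selected
  splits shared across representations, six metrics (accuracy, sensitivity,
  specificity, PPV, F1, rank-statistic AUROC), percent(count) confusion
  matrices, paired significance tests, threshold sweeps (0.1–0.9) and
  training-size sweeps (25–100%).

See `docs/methods.md` for the underlying model, parameter defaults with
units, numerical conventions, and known limits.

## Worked example

A miniature end-to-end run (4 simulated trials of 30 s, one split,
random-forest model only):

```python
from fetalmotion.pipeline import RunConfig, run_experiment
from fetalmotion.synthetic import SimConfig

cfg = RunConfig(sim=SimConfig(trial_duration=30.0), n_trials=4, n_splits=1,
                n_test=1, n_val=1, seed=0, models=("rf",), rf_search_budget=2)
df = run_experiment(cfg)
print(df[["model", "modality", "auroc", "accuracy", "sensitivity", "f1"]])
```

prints (one row per model × modality × split; exact values for seed 0):

```
model modality  split_id  auroc  accuracy  sensitivity  specificity    f1
   rf      acc         1  0.228     0.800        0.000         0.98 0.000
   rf      gyr         1  0.725     0.833        0.091         1.00 0.167
   rf combined         1  0.325     0.817        0.000         1.00 0.000
```

Each row is the model's test-set performance on one held-out trial: AUROC is
the threshold-free ranking quality (0.5 = chance), and the other metrics are
taken at threshold 0.5.  At this toy scale a single 30 s test trial contains
only a handful of perceived events, so the numbers swing widely between
seeds — which is precisely why the package evaluates medians across
Monte Carlo splits and cohort seeds at larger scales (the acceptance tests
use 14 trials × 100 s × 3 seeds).

The same pipeline is scriptable from the shell:

```bash
fetalmotion simulate --n-trials 4 --seed 0 --out cohort/
fetalmotion label --in cohort/trial_000.h5 --out labels.csv
fetalmotion all --config run.yaml --out results/
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's acceptance-target
quantities from scratch — it simulates a recording, preprocesses it, applies
the canonical feature extractor to one 0.5 s five-sensor window and counts
the emitted features — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
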