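# sleepsense

Interpretable prediction of **perceived sleep quality** from wrist-wearable
biosignals.

People rate their own sleep each morning on a 1–5 Likert scale, and that
perception — not just objective sleep architecture — drives next-day mood,
fatigue and quality of life.  `sleepsense` is a tested, reusable pipeline
for modeling those morning ratings from the signals a commodity wrist
device records overnight and through the surrounding day: blood volume
pulse (BVP, 64 Hz), electrodermal activity (EDA, 4 Hz), 3-axis wrist
acceleration (32 Hz) and skin temperature (4 Hz), alongside a simple sleep
diary.  It is written for researchers running intensive-longitudinal field
studies with Empatica-E4-class devices who want explainable models rather
than black boxes.

## What the pipeline does

1. **Signal ingestion** (`signal_io`) — E4-style CSV exports, device IBI
   files, diaries and feature tables; all times UTC seconds; half-open
   windows throughout.
2. **Feature extraction** — 52 interpretable per-night features:
   * 24 cardiac: {HR, RMSSD, SDNN, SD2} × {mean, max, min} × {awake,
     asleep}, from 5-minute windows (2.5-minute overlap) of either the
     device's own inter-beat intervals (*dataset A*) or beats detected in
     the band-passed BVP (*dataset B*).  HR = 60000/mean(IBI), RMSSD =
     √mean(ΔIBI²), SDNN = population SD of IBIs, SD2 = √(2·SDNN² − SDSD²/2)
     — the Poincaré-plot long axis.  Windows with missing or low-quality
     beats are dropped, never interpolated.
   * 12 EDA: level and least-squares-slope statistics per phase, after
     three per-second validity rules (contact loss < 0.05 µS; flatline
     ≤ 0.01 µS/s; physiologically impossible change outside +20%/−10% per
     second).
   * 4 actigraphy: sleep duration, sleep-onset latency, and summed activity
     counts per phase, with sleep/wake scored per minute by both the Sadeh
     and Cole-Kripke linear rules and the diary-anchored sleep period
     averaged across the two.
   * 12 temperature: level and slope statistics per phase.
3. **Dataset construction** (`dataset`) — missing-value removal, absolute
   labeling (high iff response ≥ 4) and **per-participant normalized**
   labeling (features z-scored within participant; high iff the night beats
   the participant's own mean response), plus label-balance and
   between/within-participant variance diagnostics.
4. **Modeling** (`modeling`) — a tree ensemble, a GLM (logistic regression)
   and a GAM (per-feature spline smooths), evaluated by
   leave-one-participant-out cross-validation repeated 10 times with train
   and test sets class-balanced by downsampling; balanced accuracy,
   micro-F1 and AUC on the pooled predictions; an ablation grid over the 8
   subsets of {cardiac, temperature, EDA} (actigraphy always included).
5. **Interpretation** (`interpretation`) — 100× bootstrapped centered
   partial dependence plots, density-weighted PDP feature importance, and
   smoothed misclassification-rate-per-feature-value curves that flag
   features the model overfits.

A first-class synthetic-cohort generator (`synthetic`) plants ground truth
— beat times, EDA artifact blocks, sleep periods, label-model coefficients
— so that every stage is verified by recovery.

## Worked example

Simulate a 12-participant × 20-night cohort with the default planted label
model (longer sleep raises the rating, elevated awake heart rate lowers
it), then evaluate a GLM under repeated leave-one-participant-out
cross-validation with normalized labels:

```python
import json
from sleepsense import (CohortSpec, simulate_observations, drop_missing,
                        loso_cv, ModelSpec)

spec = CohortSpec(n_participants=12, n_nights=20, seed=42)
obs, truth = simulate_observations(spec)
ds = drop_missing(obs)
res = loso_cv(ds, ModelSpec(family="glm"), n_repeats=10, seed=42,
              labeling="normalized")
print("splits:", res.n_splits)
print(json.dumps({k: round(v, 3) for k, v in res.aggregates.items()}, indent=2))
```

prints

```
splits: 120
{
  "ba": 0.81,
  "micro_f1": 0.81,
  "auc": 0.819
}
```

Every participant is held out 10 times (12 × 10 = 120 splits).  The planted
effects are strong (|standardized coefficient| 1.0, noise SD 0.5), so the
model recovers them well above chance: balanced accuracy 0.81 — which on
perfectly balanced test sets equals plain accuracy and micro-F1 — and AUC
0.82.  Shuffling the responses drops balanced accuracy to ≈ 0.5 (see the
permutation check in the test suite).

The same pipeline runs from the shell on E4-style directories:

```bash
sleepsense simulate --out cohort/ --seed 7
sleepsense extract --session-dir cohort/ --diary cohort/diary.csv --out table.csv
sleepsense evaluate --table table.csv --labeling normalized --family tree_ensemble
sleepsense explain --table table.csv --top 12 --out pdp_panel.png
```

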