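# myoscore

Continuous single-cell differentiation scoring from tracked-cell
dynamics, with downstream state-timing estimators and random-field group
inference — plus a synthetic trajectory simulator so the whole pipeline
is exercisable without any imaging data.

## The problem

Primary myoblasts induced to differentiate (e.g., by ERK1/2 inhibition)
transition from proliferating precursors to post-mitotic, fusion-competent
myocytes and then fuse into multinucleated myotubes. The transition is
gradual and asynchronous across cells, so a population-level readout
hides the single-cell dynamics. `myoscore` infers each cell's position
along the transition from its own behaviour over time: cells slow down
and become more persistent as they differentiate, and their F-actin
signal rises.

## The method

1. **Temporal segments.** Each cell track (nuclear positions every
   5 min, optional per-frame actin-window statistics) is cut into
   overlapping windows of 2.5 h (31 frames, lag 1 frame). Per segment,
   the motility series is the per-step displacement
   (dx_t, dy_t) = (x_t − x_{t−1}, y_t − y_{t−1}); the actin series is
   the five window statistics (min, max, mean, median, std).
2. **Features and selection.** A fixed catalog of 30 named temporal
   features per channel (statistics, derivatives, autocorrelations,
   peaks, run lengths, trend, complexity). Feature selection: per-feature
   Mann–Whitney U tests corrected by the Benjamini–Yekutieli FDR
   procedure at α = 0.05.
3. **State classifier.** A random forest (grid-searched over the
   documented hyperparameter optima with 5-fold stratified CV maximizing
   ROC AUC) trained on labeled segments: "differentiated" = the
   2.5 h window of a differentiating cell ending at the culture's
   first fusion (fixed default 12.3–14.8 h); "undifferentiated" =
   non-overlapping windows tiled over control cells. The forest's
   class probability for "differentiated" is the **differentiation
   score** s(t) ∈ [0, 1], one value per sliding segment, giving a
   per-cell score trajectory.
4. **State timing.** Run-length rules on s(t): onset = last time of the
   longest run with s ∈ [0.2, 0.3]; high-stable point = first time of
   the longest run with s ∈ [0.7, 0.8]; duration = their difference;
   terminal differentiation = first time of the longest run with
   s > 0.78. Monotonicity is the per-cell Spearman ρ of s vs t over
   7.5–14.5 h. Fusion coupling: per-cell gap between annotated fusion
   and estimated terminal time, Pearson r, D'Agostino normality tests.
5. **Group inference.** Score trajectories of two conditions are
   compared as 1D random fields: Gaussian smoothing, node-wise
   two-sample t field, smoothness (FWHM) from normalized residuals, and
   an expected-Euler-characteristic critical threshold u* controlling
   the family-wise error over each time interval; supra-threshold
   clusters get Monte-Carlo p-values.
6. **Baselines.** Single-measurement classifiers (local density within
   50 µm, speed, mean actin, actin derivative, migration persistence,
   and all four combined) trained on per-segment means, for the contrast
   "discriminates conditions" vs "yields a monotone per-cell score".

## Worked example

```python
from myoscore.pipeline import run_study, timing_recovery, monotonicity_summary

study = run_study(n_cells=150, seed=0)          # simulate, train, score
print(study.heldout_metrics["motility"]["auc"]) # 0.955
rec = timing_recovery(study, "motility")
print(rec["onset_abs_err_median_h"])            # 1.90
print(rec["terminal_abs_err_median_h"])         # 0.92
print(rec["fusion_gap_median_h"])               # 3.75
print(rec["pearson_terminal_fusion"])           # 0.92
print(monotonicity_summary(study, "motility")["rho_median_diff"])  # 0.73
```

`run_study` simulates two independent experiments (150 differentiating
"ERKi" + 150 proliferating "DMSO" cells each), trains motility/actin/
combined classifiers on one and scores the other. The printed numbers
say: held-out discrimination AUC 0.96; the run-length estimators recover
each simulated cell's true onset and terminal-differentiation times to
median errors of 1.9 h and 0.9 h; the estimated terminal-to-fusion gap
(median 3.75 h) is close to the generative 3 h and correlates strongly
with the true fusion time (r = 0.92); and the median per-cell score-time
Spearman ρ of 0.73 shows the score rises monotonically as cells
differentiate (controls sit near 0).

The same pipeline is scriptable from the shell:

```bash
myoscore simulate --n-cells 50 --seed 1 --out tracks.csv --truth truth.csv
myoscore segment  --tracks tracks.csv --label --out segments.csv
myoscore train    --segments segments.csv --mode motility --out model.joblib
myoscore score    --model model.joblib --tracks tracks.csv --out scores.csv
myoscore metrics  --scores scores.csv --out timings.csv
```

## Limitations

See `docs/methods.md` for the model's assumptions, the synthetic
generator's scope (what passing tests do and do not imply about real
imaging data), and known limitations of the run-length duration
estimator on low-noise data.
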