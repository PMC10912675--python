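# Methods

This note documents the models, parameters and numerical choices behind
`myoscore`, and what the synthetic experiments do and do not demonstrate.

## Pipeline model

The central object is the per-cell **differentiation score trajectory**:
the class probability that a random-forest classifier assigns to the
"differentiated" state for each sliding 2.5 h window of a cell's track.
The score is used as a continuous, monotone proxy for the cell's
position along the myoblast→myocyte transition. Monotonicity, not
linearity, is the operative assumption: downstream estimators only ask
when the score enters and leaves bands, so no probability calibration is
applied (and none should be — calibration would change band dwell times
without adding information).

### Segmentation and labels

- Segment length L = 31 frames: 2.5 h at 5-min sampling spans 30
  intervals, so a window containing both endpoints has 31 frames; the
  per-segment displacement series then has 30 entries and the actin
  series 31.
- Training labels: one positive window per differentiating cell — the
  segment spanning the label window (default fixed 12.3–14.8 h;
  alternatively the 2.5 h ending at an annotated first-fusion time).
  Controls are tiled with non-overlapping negative windows across the
  whole experiment. Perturbation conditions are never labeled. We use a
  single positive window per cell; a multiplicity rule for positives
  (several overlapping windows per cell) would only duplicate nearly
  identical rows.
- On synthetic experiments the fixed window is preferred over the
  first-fusion anchor: the minimum fusion time over 150 simulated cells
  lies in the distribution's extreme tail and can precede most cells'
  onset, which would poison the positive labels.

### Feature catalog

30 features per channel (channels: dx, dy displacements; the five actin
window statistics), all with stable names: mean, std, median, min, max,
skewness, kurtosis (both imputed 0 on constant series), absolute energy
Σx², mean absolute change, mean change, variance of the first
difference, autocorrelation at lags 1/2/5/10 (imputed 0 when the series
is constant or shorter than lag+2), peak count with support 3 (a point
strictly above its three left neighbours and at least as high as its
three right neighbours, so a flat top counts its left edge), longest run
above/below the mean, count above the mean, linear-trend slope and
standard error, complexity CE = sqrt(Σ(x_{t+1}−x_t)²), quantiles
0.1/0.25/0.75/0.9, and first/last location of max/min normalized to
[0, 1]. An explicit catalog (rather than an external feature library)
guarantees reproducible column names and values across environments;
population std (ddof 0) is used throughout.

### Feature selection

Per-feature two-sample Mann–Whitney U (no normality assumption on
temporal features), Benjamini–Yekutieli step-up at α = 0.05
(`statsmodels` `fdr_by`), valid under the arbitrary dependence that
temporal features exhibit. Degenerate (constant) features receive p = 1.
If nothing survives — possible on tiny training sets — the classifier
falls back to the full catalog rather than failing.

### Classifier

`RandomForestClassifier` grid-searched over max_depth {12, 20} ×
n_estimators {100, 200} × min_samples_leaf {1} (the documented optima of
the motility and actin models plus their cross-combinations; a wider
neighbourhood multiplies training cost without moving the selected model
on data this separable) with stratified 5-fold CV maximizing ROC AUC,
refit on all data, fixed seed. Scores are the positive-class tree-vote
fraction. Evaluation reports AUC (rank-based) plus accuracy/precision/
recall at threshold 0.5.

## Timing estimators

All estimators are run-length rules with inclusive band membership
([0.2, 0.3] and [0.7, 0.8]) and a strict terminal threshold (> 0.78);
among equal-length runs the earliest wins (the rules need a
deterministic tie-break; earliest is the only order-free choice).
Trajectory timestamps sit at the segment's final frame — the moment the
score becomes available; any fixed within-window convention shifts all
timing outputs by a constant and cancels in durations and gaps. The
score-time Spearman window (7.5–14.5 h) is evaluated against these
segment-end timestamps.

## Synthetic experiments

The generator emulates a two-condition live-imaging experiment
(conditions named ERKi = differentiating, DMSO = proliferating control):

| parameter | default | meaning |
|---|---|---|
| n_cells_per_condition | 150 | founders per condition |
| imaging window | 1.5–23 h | treatment at t = 0 |
| frame interval | 5 min | 259 frames |
| field | 1500 × 1500 µm | reflective boundaries |
| speed undiff → diff | 0.8 → 0.3 µm/min | mean step speed |
| heading σ undiff → diff | 1.2 → 0.4 rad/frame | persistence increase |
| onset | N(11, 2) h | per-cell transition start |
| duration | N(3.5, 1) h | transition length |
| fusion gap | N(3, 0.75) h | fusion − terminal |
| actin | base 100, fold 1.8, cv 0.05 | logistic rise |
| division rate (control) | 0.03 /cell/h | daughters spawned 12 µm away |

Motion is a persistent random walk whose speed and heading-noise
interpolate **linearly** across each cell's own [onset, terminal]
interval — the transition is gradual, so that monotone score recovery is
a meaningful test. The actin mean follows a logistic rise centred
mid-transition with slope k = 2·ln 9/duration, i.e. ~90 % of the rise
inside [onset, terminal], with multiplicative per-frame noise; the other
four window statistics are derived consistently (min < median < max,
std ∝ mean). After fusion, motion collapses to near arrest. Control
cells keep undifferentiated dynamics and flat actin and divide at the
stated rate; daughters appear 12 µm from the parent (≈ adjacent nuclei)
and may divide again, so control cultures grow ≈1.9× over the
experiment and local density rises. A fixed seed makes the output
bit-identical.

Image rendering (`render_actin_frames`) is an optional fixture for the
window-quantification path only: Gaussian blobs (σ = 8 µm) with peak
amplitude equal to the generative actin mean over noisy background. It
is not a microscopy simulation — no PSF, shading, bleaching or nucleus
shape.

### What the synthetic study shows — and does not

Passing tests demonstrate that the pipeline's machinery is correct and
calibrated (segmentation arithmetic, estimator/oracle agreement, FDR and
family-wise error control, determinism) and that, when the generative
assumptions hold, the score recovers per-cell onset and terminal times
and the fusion coupling. They do **not** demonstrate performance on real
imaging data: the generator has no tracking errors, no per-cell baseline
heterogeneity, no imaging drift or bleaching, and its two conditions are
far better separated than real cultures.

Two known consequences on clean synthetic data:

- **Duration compression.** The run-length duration estimator measures
  the width of the score's rise. With near-noiseless features, the
  forest's confidence switches over ~0.5 h (its ambiguity region) even
  though the simulated physiological transition takes 3.5 h, so the
  estimated duration under-states the configured one. On noisier data
  the score rise widens toward the real transition; the estimator is
  faithful to its definition either way.
- **Monotone baselines.** The synthetic actin mean is itself a clean
  monotone sigmoid, so a baseline classifier built on per-segment mean
  actin produces an almost equally monotone score. The
  discrimination-without-monotonicity contrast therefore shows up
  clearly for the density baseline (AUC above chance, per-cell ρ ≈ 0)
  but not for actin-containing baselines. Likewise the density baseline's
  discrimination is weak at the default field density (~0.5 expected
  neighbours within 50 µm): the ≈1.9× proliferation growth is small
  against Poisson spread at segment scale.

## Random-field inference

- Smoothness: per-node-normalized residuals; v = mean squared
  node-to-node gradient; FWHM = sqrt(4 ln 2 / v). White noise gives
  FWHM ≈ 1.18 nodes; noise smoothed with a Gaussian of width σ gives
  ≈ sqrt(8 ln 2)·σ. Zero-variance nodes are excluded.
- Critical threshold: solve α = S_t(u; ν) + R·(sqrt(4 ln 2)/2π)·
  (1 + u²/ν)^{−(ν−1)/2} with R = (nodes − 1)/FWHM resels, by bracketed
  Brent root finding (tolerance 1e-6). As R → 0 this reduces to the
  pointwise t quantile; it can only exceed it.
- The comparison is two-sided on |t| (score differences can go either
  way under perturbations), so the per-tail threshold is computed at
  α/2; simulated null calibration confirms a family-wise error near the
  nominal 0.05.
- Cluster-level p-values use Monte Carlo under the fitted FWHM
  (two-group Gaussian trajectories smoothed to that width, default 10⁴
  fields, seeded) rather than a closed-form extent approximation: it is
  directly calibratable and avoids extra distributional assumptions.
  Set-level p keeps the parametric form, doubled for two-sidedness.
- Default trajectory smoothing before inference: Gaussian σ = 2 frames
  (configurable); intervals default to 4–10, 10–16, 16–22 h.

## Registration and actin windows

Stage drift is estimated from the tracks themselves: the per-frame-pair
median displacement over shared cells (robust to a minority of fast
movers), accumulated from frame 0. Precomputed offsets (e.g. from
image-based optical flow) can be supplied via CSV instead. A degenerate
consequence, by construction: a single moving cell is read as drift.
Actin windows are 32 µm squares → round(32/0.462) = 69 px at the default
pixel size, centred on the nucleus pixel (odd side keeps the centre
symmetric); border windows are clipped, not discarded.

## Numerical conventions and degenerate inputs

- Coordinates in µm, image convention (y down), frames 0-based, t = 0 at
  treatment; tracks must be gap-free for segmentation (a gap raises an
  error naming the cell; a short track is skipped with a warning).
- Constant score trajectories: Spearman ρ is undefined and reported as
  (0, 1) — no monotone association.
- Persistence 0/0 (a cell that never moved) is defined as 0; local
  density uses an inclusive radius and excludes the focal cell, and is
  computed within condition groups (conditions are separate cultures).
- `fusion_coupling` needs ≥3 annotated pairs; normality p-values are NaN
  below n = 8 (the K-squared test's minimum).
- Problem sizes in tests and the acceptance script (150 cells per
  condition per experiment; 1000-replicate null calibrations;
  2000-replicate smoothness checks) were chosen as the smallest sizes at
  which the Monte-Carlo standard errors are well inside the asserted
  tolerances.

## Known limitations

- The duration estimator's compression on low-noise data (above).
- Onset/terminal estimates are undefined for cells whose score never
  dwells in the respective band; summaries are over cells with defined
  estimates, and the defined fractions are reported.
- The forest is not calibrated, so score values between bands have no
  probabilistic interpretation beyond ordering.
- The drift estimator conflates collective migration with stage drift;
  supply image-derived offsets when collective motion is expected.
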