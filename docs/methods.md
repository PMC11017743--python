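# Methods

`spontact` detects spontaneous and stimulus-evoked activity of sensory
neurons in in-vivo calcium-imaging traces recorded with slow genetically
encoded indicators (GCaMP6s).  This note documents the models, the
simulator, the numerical choices, and what the test suite does and does not
establish.

## The detection problem

Dorsal root ganglion (DRG) neurons fire spontaneously at low rates
(< 1 Hz) in inflammatory pain states.  With a slow indicator each action
potential produces a fluorescence transient with ~0.2 s rise and ~1.5 s
decay, and sustained firing above roughly 0.5 Hz saturates the indicator.
Ground truth for "spontaneously active" comes from a lidocaine nerve block:
applied between the inflamed periphery and the ganglion, it silences
peripherally generated firing, so a neuron whose transients disappear after
the block was genuinely active.  The package's classifiers are trained on
segments labeled this way and then applied to recordings where no block is
available.

## Pipeline

1. **Background subtraction** — a per-frame background series (from an
   empty region of the field) is subtracted from every trace.
2. **ΔF/F0** — `100·(Ft − F0)/F0` per neuron.  F0 is the mean of the first
   2 s (default) or a whole-trace percentile (10th) for recordings that
   begin mid-transient.  When F0 < 1, the denominator — never the
   numerator — is clamped to 1 so dim neurons cannot produce arbitrarily
   amplified traces.  Whether a running or single-window baseline is more
   faithful for 1-photon data is genuinely open; both are exposed, the
   fixed window is the default.
3. **Smoothing** — centered moving average over `round(window·rate)`
   frames, shrinking at the edges so no invented samples enter classifier
   features.  Default window 1 s.
4. **Resampling** — plain linear interpolation onto the target grid
   (no anti-alias filter, matching the established workflow); the new grid
   spans the same interval with `floor(span·rate) + 1` frames.  When both
   smoothing and resampling are requested, smoothing runs first.

### Why smoothing is part of the classifier input contract

The cross-laboratory workflow harmonizes 32-Hz two-photon data by smoothing
(1 s) and downsampling to 3.65 Hz before scoring.  Smoothing changes the
noise *spectrum*: white per-frame noise becomes strongly autocorrelated.
A forest trained on unsmoothed traces can learn that "uncorrelated noise
floor = inactive", a rule that inverts on smoothed inputs — on synthetic
data this collapses the spectral ensemble's accuracy from 1.00 to 0.25.
The package therefore applies the same 1-s smoothing to *training* traces
and to every test input in the cross-recording workflow, so the noise
bandwidth is matched on both sides at any acquisition rate.  Native-rate
accuracy is unaffected (the transients are far slower than the window);
cross-rate transfer becomes stable.

## SD-threshold comparator

The historical rule: a neuron is active when its ΔF/F0 trace exceeds
`mean + k·SD` on more than `min_occasions` occasions within a 5-minute
window (defaults k = 2.5, 30 occasions, 300 s; sample SD).  "Occasion" is
not defined in the literature that uses this rule; the default here is an
upward crossing (sample above threshold whose predecessor is at or below),
which prevents one long transient from counting as hundreds of occasions.
A `sample_above` variant exists for sensitivity analysis.  Recordings
longer than the window are evaluated on the first window (the training-
segment convention); shorter ones scale the occasion requirement
proportionally, rounded up.  Zero-variance traces are labeled inactive
with a warning.  The rule's weakness — the SD distributions of active and
inactive neurons overlap — is reproduced by the pooled simulated cohort.

## Interval forests

Both classifiers are ensembles of CART decision trees over features of
random time intervals, built from scratch over scikit-learn trees.

**TSF (time series forest).**  Each of `n_trees` trees draws `√m` random
intervals (length ≥ 3) of the m-frame series; each interval contributes its
mean, standard deviation and least-squares slope; the tree is fitted on the
3·√m features with per-node random feature candidates (`max_features =
"sqrt"`), following the original design.

**RISE (random interval spectral ensemble).**  Each tree owns a single
random interval (the first tree always sees the whole series; minimum
length 16) described by spectral features: autocorrelation coefficients up
to lag `min(100, L−1)`, Yule-Walker autoregressive coefficients of order
`min(12, L/4)` (computed by a row-vectorized Levinson-Durbin recursion on
biased autocovariances; zero-variance rows yield zero features), and
periodogram power at the first `L/2` nonzero frequencies.  Blocks are
zero-padded to the sizes of the full-series interval so every tree sees one
fixed vector length.  RISE trees are plain best-split CART (no feature
subsampling), again following the original design.  This asymmetry matters
empirically: RISE's lag- and bin-indexed features make it sensitive to
time-axis warps (accuracy collapses when test data are resampled to 2 Hz),
while TSF's amplitude summaries are robust — the characteristic pattern of
the two algorithms.

Defaults: 500 trees each (the canonical published default; the acceptance
checks use 200 for runtime — measured accuracies are identical from 100
up).  Trees are unweighted by default, mirroring the original protocol on
the imbalanced 272:1036 class ratio; a `class_weight="balanced"` flag
exists.

**Training protocol.**  From each lidocaine recording: *active* segments
are the first 1100 frames (~5 min at 3.65 Hz) of neurons the block
confirmed as spontaneously active; *inactive* segments are the last 1100
frames (> 5 min post-block) of those same neurons **and** of neurons that
were never active (so the inactive class includes non-nociceptor baselines);
neurons with ambiguous block response are excluded.  Class counts and the
imbalance ratio are recorded in the model metadata.

**Contracts.**  A model refuses test inputs longer than its training
segments (the frame-budget rule, stated verbatim in the error).  Shorter
inputs are right-padded with their edge value, with a warning.  Tie votes
go to the inactive class — the conservative call for a screening tool.
Sampling-rate mismatches beyond 2% warn at the library level; the CLI
downsamples automatically by linear interpolation.

**Cross-validation.**  Stratified k-fold (default k = 5, stratification
chosen so every fold sees both classes).  How a published 80:20 split
interacts with 5-fold CV is ambiguous; implemented as: optionally hold out
20% (stratified), run the CV on the remaining 80%, report both.

## Evoked-response detection

Per neuron and stimulus epoch, on the 1-s-smoothed trace: Fb and Fb_max are
the mean and maximum over a baseline window running from 1 s after the
recording start (or after the previous epoch's grace period, so earlier
responses cannot contaminate the baseline) to 1 s before stimulus onset.
A response is positive when the peak within [onset, offset + 1 s grace]
exceeds `Fb + (Fb_max − Fb)·x` *and* the longest contiguous run above that
threshold lasts ≥ 0.5 s.  x defaults to 2.5, the midpoint of the
conventional 2–3 range; values outside [2, 3] warn.  Duration is measured
as contiguous time above threshold — the strictest reading of the brevity
exclusion.  A flat baseline (Fb_max = Fb) degenerates to threshold = Fb,
and any sufficiently long excursion counts.  The 1-s post-offset grace
accommodates the indicator's lag.  x is applied per run (per-recording vs
per-neuron choice is not standardized; configurable).

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total, counted against ground-truth labels with ambiguous neurons
excluded from both sides.  Zero-denominator ratios are reported as NaN with
a flag, never as 0 or 1.  Per-recording proportions of active neurons are
compared across groups with an unpaired Student t test (pooled variance;
Welch optional), reported as mean ± SEM.  Two zero-variance groups with
equal means return t = 0, p = 1, flagged as degenerate.

## The simulator

Forward model per neuron i on the frame grid t = 0, 1/rate, …, ≤ duration
(`floor(duration·rate) + 1` frames; 301 s at 3.65 Hz → 1099):

    raw[i,t] = b_i · (1 + drift_i(t) + artifact(t) + u_i(t)) · (1 + S_i(t)/100) + ε

* **Spikes** — a fraction of neurons (rounded count) is active; each draws
  a rate uniformly from 0.1–0.5 Hz (the low-rate inflammatory regime) and a
  homogeneous Poisson train; bursting is out of scope.  Active neurons are
  guaranteed ≥ 1 spike so labels and spike trains agree.  Active neurons
  are peripherally driven: a lidocaine event truncates their spikes.
* **Indicator** — S_i is the train convolved with a difference of
  exponentials (rise 0.18 s, decay 1.5 s, peak-normalized to 30 %ΔF/F0 per
  spike), hard-capped at 300 %ΔF/F0.  The cap is `min(sum, ceiling)` rather
  than a Hill function — simpler, exactly testable, and adequate for
  classification.  These kinetics are simulator defaults chosen to
  reproduce the slow-indicator regime (saturation near 0.5 Hz sustained
  firing), not measured values; all are exposed in the config.
* **Baseline** — b_i ~ Normal(100, 20) a.u., floored at 0.001.
* **Drift** — one slow sinusoid per neuron (period ≈ recording length,
  random phase), amplitude 2% of baseline.
* **Correlated noise** — u_i is a stationary Ornstein-Uhlenbeck process
  (SD 2 %ΔF/F0, correlation time 1 s): the hemodynamic/residual-movement
  baseline fluctuation real recordings always carry.  Without it every
  inactive trace is spectrally white, an accidental regularity that
  classifiers exploit and that no real cohort guarantees.
* **Shared artifacts** — movement is recording-wide: Poisson events
  (0.5/min) of tapered random-walk bursts (0.5–3 s) multiplying all
  baselines, amplitude ~5%.
* **White noise** — i.i.d. Gaussian per frame, SD 5% of each neuron's
  baseline; frames are clipped at zero.  Per-frame white noise should scale
  with √rate when the same preparation is simulated at a different
  acquisition rate (equal photon budget per unit time).
* **Evoked responses** — each epoch adds a kernel-shaped transient at onset
  (default 100 %ΔF/F0, configurable) to responding neurons (per-epoch
  Bernoulli with the configured probability); responders are recorded in
  the ground truth.

The simulated **cohort** (`generate_training_cohort`) emulates an
8-animal training set with heterogeneous noise: white 3–12%, slow 2–10%
with correlation times 0.5–3 s, artifacts 0.3–2/min — spanning quiet,
well-clamped preparations and movement-heavy or dim ones.  This diversity
is what real multi-animal training data provide and what prevents the
forests from treating any single noise signature as the marker of
inactivity.

**What the simulator does not emulate:** photon-physics (shot noise is
Gaussian, not Poisson), image-plane structure (ROIs, neuropil
contamination), bursting, somatically generated activity that survives a
nerve block, and indicator nonlinearity beyond the hard cap.  A green test
on synthetic data therefore establishes that the pipeline implements its
rules correctly and behaves sensibly in a realistic regime — not that it
reaches any particular accuracy on real recordings, whose difficulty
(label noise, borderline firing rates, optical artifacts) the clean
simulator understates: simulated accuracies here are near 1.0, while
real-data accuracies for this kind of pipeline are in the 80–95% range.

## Numerical choices

* Frames are 0-based; segments are half-open `[start, end)`.
* Sample (n−1) SD in the SD rule and summaries; population SD inside TSF
  features (a feature convention, not an estimator).
* ACF uses biased (1/L) autocovariances — the convention under which the
  Levinson recursion is stable and matches Yule-Walker "mle".
* Degenerate traces: zero variance → zero ACF/AR features; SD rule labels
  inactive with a warning; ΔF/F0 with F0 = 0 and clamping disabled is a
  per-neuron error.
* Determinism: every stochastic component (simulator, interval sampling,
  tree seeds, CV shuffles) derives from explicit integer seeds; identical
  seeds give bit-identical traces, models and predictions.
* Model archives are zip files (JSON metadata + joblib tree store) with a
  format version checked on load.

## Known limitations

* The forests assume a fixed input length; variable-length prediction is
  handled only by edge-padding shorter inputs.
* The SD rule's published form leaves "occasion" and the SD window
  underspecified; results are sensitive to that choice (documented
  defaults).
* Group comparisons implement the two-sample t test only — the design used
  for per-recording proportions — not mixed models over neurons.
* The 2-Hz degradation pattern (spectral ensemble degrades, summary forest
  does not) is reproduced qualitatively; its magnitude depends on how
  separable the two classes are and is smaller on clean synthetic data
  than on real recordings.
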