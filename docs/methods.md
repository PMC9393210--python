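# Methods

`fhrfusion` implements a mixed-data-type classifier for 2 Hz fetal heart
rate (FHR) recordings: quantitative cardiotocography (CTG) regressors feed
an MLP branch, signal-to-image encodings feed a CNN branch, and the two are
fused into a single two-class (healthy vs. pathological) model.  This note
records the model, its assumptions, every parameter with units and
defaults, what the synthetic generator does and does not emulate, and the
numerical choices that make the results reproducible.

## Signal model and preprocessing

An FHR record is a sequence of beats-per-minute readings sampled at
2 Hz (120 samples per minute).  Readings outside the physiological
validity range **[50, 220] bpm** (default; configurable), and zero
readings in particular, are treated as transducer signal loss.

Repair rules:

- **Interpolation** — invalid runs strictly shorter than **15 s**
  (30 samples) are replaced with a linear ramp between the flanking valid
  values, so interpolated values always lie between those neighbours.
- **Splicing** — runs of 15 s or longer, and invalid runs touching either
  end of the record, are removed and the remainder concatenated.  Splicing
  first, then segmenting, is a package choice; the alternative order is
  equally defensible but produces different segment boundaries.
- **Segmentation** — the repaired trace is tiled from offset 0 into
  non-overlapping **20-minute segments of exactly 2400 samples**; the
  remainder is discarded.  Segments in which more than **10%** of samples
  are interpolated (`quality_cap=0.10`) are rejected as too corrupted.

## The 15-feature suite

Features are computed per segment.  Time-domain variability indices use
the **T24 interbeat-interval series**: the segment is divided into 2.5-s
blocks (5 samples), and each block contributes one interval
`T = 60000 / mean(bpm)` in ms — 24 values per minute, 480 per segment.

Per minute `j` with 24 values, averaged over the 20 minutes:

- **STV** (ms): mean of `|T(i+1) − T(i)|` (23 first differences).
- **DELTA** (ms): max − min of the minute's intervals.
- **II** (unitless): standard deviation of `|ΔT|` divided by STV(j).
- **LTI** (ms): interquartile range of `m(i) = sqrt(T(i)² + T(i+1)²)`
  over non-overlapping 3-minute windows, averaged.

Spectral powers are computed from the interval signal in ms (2 Hz) with
**Welch's method** (Hann window, 240-sample/2-min windows, 50% overlap,
linear detrend) and integrated (trapezoid) over:

- **LF** 0.03–0.15 Hz, **MF** 0.15–0.5 Hz, **HF** 0.5–1.0 Hz (all ms²),
- **ratio** = LF / (MF + HF), undefined (NaN) when the denominator is 0
  (a NaN ratio is mapped to 0 when assembling the feature vector).

The Nyquist frequency at 2 Hz is exactly 1.0 Hz, so the HF band upper
edge is the last attainable frequency bin.

**Approximate entropy** (ApEn, nats) uses the Pincus convention on the
480-value interval series: embedding `m = 2`, tolerance `r = 0.2 × SD` of
the series, Chebyshev distance, self-matches included; constant series
(SD = 0) are assigned ApEn = 0.  The vectorized implementation is held to
an O(N²) brute-force oracle at 1e-12 in the tests.

**Baseline (FHRB, bpm)** uses a simplified iterative Mantel-style
estimator: a 2-minute masked moving average, iterated (≤10 times or until
the estimate changes < 0.1 bpm) while excluding excursion samples.
Exclusion is hysteretic: any sample deviating more than **10 bpm** from
the current baseline seeds the exclusion of its entire contiguous run of
samples deviating more than **5 bpm**.  The run-expansion step is a
package design choice beyond plain per-sample exclusion: without it the
shoulders of deep decelerations (deviations between 5 and 10 bpm) remain
in the window mean and bias the baseline by 2–3 bpm into the event, which
is enough to break exact event-count recovery at the margins promised
below.  FHRB is the mean of the converged baseline.

**Events** are counted against that baseline with strict inequalities:

- acceleration candidate: maximal run with deviation > **10 bpm** lasting
  ≥ **15 s**; **large** if its peak deviation exceeds **15 bpm**, else
  **small** (each event counted once);
- deceleration: maximal run below baseline that sustains deviation
  > **20 bpm** for ≥ **30 s**, or > **10 bpm** for ≥ **60 s**.

A practical limit: the 2-min baseline window cannot separate a shallow
excursion that fills most of the window (e.g. −14 bpm for 65 s on an
otherwise flat trace), because no sample ever deviates > 10 bpm from the
dragged-down first-pass mean.  The shallow-long clause is therefore
exercised against a known baseline in the tests; end-to-end recovery
guarantees (below) apply to events with comfortable margins.

The remaining two features are metadata: gestational week and maternal
age.  The 15 features are min-max normalized to [0,1] per column with
statistics learned on the training partition only; out-of-range test
values are clipped, and constant columns map to 0 with a warning.

## Signal-to-image encodings

Each segment maps to eight 64×64 images in [0,1].  Pairwise encodings
(GASF, GADF, MTF, S, R) first reduce the 2400-sample series to 64 points
by piecewise aggregate approximation (PAA; the remainder folds into the
last block).  All images are finalized by min-max scaling and bilinear
resizing to 64×64.

- **GASF / GADF** — rescale to [−1,1], take `φ = arccos`, then
  `cos(φ_i + φ_j)` (symmetric) / `sin(φ_i − φ_j)` (antisymmetric, zero
  diagonal).
- **MTF** — 8 quantile bins; row-normalized one-step transition matrix W
  from successive pairs (empty rows set uniform); field
  `F_ij = W[state(i), state(j)]`; optional mean-pooling over m×m patches.
- **S / R** — pairwise absolute-distance matrix S, and its binarization R
  with threshold ε defaulting to the 20th percentile of off-diagonal
  distances.
- **CWT** — Morlet continuous wavelet transform at 64 scales spaced
  geometrically over pseudo-frequencies 0.01–1 Hz.
- **PS** — short-time power spectrogram: Hann window of 120 samples
  (1 min), 50% overlap, `|rfft|²/window_length`.  The framing is done by
  hand (sliding windows + rfft) precisely so that the one-sided per-frame
  Parseval identity holds exactly: DC + 2×(interior bins) + Nyquist
  equals the windowed frame energy to 1e-6 relative.
- **PSP** — persistence spectrum: for each frequency bin, a histogram of
  how often its power (in dB, floored at −120 dB) falls in each of 64
  power bins across frames; total mass equals frames × frequency bins.

The default CNN input stack is **(GADF, PS, PSP)**, configurable.

## Classifier

Built on a compact NumPy neural-network engine (float32, seeded,
deterministic on one thread) providing dense, valid-padding conv (im2col),
2×2 max-pool, batch-norm (momentum 0.9), inverted dropout, softmax,
categorical cross-entropy, and Adam.

- **MLP branch**: 15 → 500 → 250 → 150 → 50 → 2 softmax; ReLU throughout;
  dropout 0.4 after hidden layers 1, 2 and 4; L1 = 1e-5 and L2 = 1e-4
  kernel penalties on hidden layer 3.
- **CNN branch**: two conv blocks (16 then 32 filters of 5×5, valid
  padding, each batch-normalized and 2×2 max-pooled), dropout 0.8,
  flatten (64→60→30→26→13 gives 13·13·32 = **5408**), dense 64 with
  batch-norm and dropout 0.8, dense 16, 2-way softmax.
- **Combined model**: the branches' 2-unit softmax outputs are
  concatenated (4 fusion inputs) into a 128-unit ReLU layer and a 2-way
  softmax.  A configuration switch fuses the penultimate layers
  (50 + 16 = 66 inputs) instead.

Training: Adam with initial learning rate **1e-4** and per-epoch
hyperbolic decay `lr(e) = lr₀ / (1 + 5e-7·e)` (decay = 1e-4/200, so the
rate is effectively constant at these epoch counts), batch size 32, at most 50
epochs, early stopping on a stratified 10% validation split with patience
2 and best-weight restoration.  Two-class categorical cross-entropy on the
softmax pair is identical to binary cross-entropy.

## Evaluation protocol

Positive class = pathological.  From a confusion matrix (TP, FN, FP, TN):
ACC, TPR = TP/(TP+FN), TNR = TN/(TN+FP), PPV = TP/(TP+FP),
**NPV = TN/(TN+FN)**, FPR, FNR, FDR, plus the trapezoidal ROC AUC from
positive-class probabilities.  Zero-denominator ratios are NaN, never 0.
Robustness: one fixed stratified 80/20 split, the model retrained 30 times
with distinct seeds, per-run metrics collected; architectures compared by
a two-sample **Welch t-test** on per-run accuracies at α = 0.01.

## Synthetic data generator

Each record is an additive construction with fully logged ground truth:

- baseline: per-record level ~ N(140, 8²) bpm plus a 2-bpm sinusoidal
  drift (12-min period, random phase);
- variability: Gaussian noise band-pass filtered (4th-order Butterworth,
  forward-backward) to each of the LF/MF/HF bands and scaled to
  configured variances — defaults 9 / 2 / 0.8 bpm² (healthy);
- events: Poisson counts per 20 min (accelerations 3.0, decelerations
  0.3), raised-cosine bumps with amplitude/duration ~ N(18, 3²) bpm /
  N(40, 10²) s for accelerations and N(30, 5²) bpm / N(90, 15²) s for
  decelerations, placed with ≥30 s separation so excursions never merge.
  A raised-cosine of amplitude `a` and width `T` exceeds a threshold θ<a
  for the closed-form duration `T·(1 − arccos(1 − 2θ/a)/π)`, which makes
  threshold margins analytic;
- gaps: Poisson (2 per 20 min) zero-reading spans ~ N(6, 3²) s;
- metadata: gestational week ~ U(32, 40), maternal age ~ N(31, 5²)
  clipped to [18, 45], identically distributed in both classes so the
  labels carry no metadata shortcut.

Default class contrast (pathological vs. healthy): band powers × 0.5,
acceleration rate × 0.25, deceleration rate × 3 — a reduced-variability,
reduced-reactivity phenotype.  A zero-contrast configuration (both classes
healthy) provides a no-signal null.

What the generator does **not** emulate: real CTG morphology (autocorrelation
beat detection artifacts, maternal heart rate capture, contraction-coupled
decelerations, sinusoidal pathology), heterogeneous pathology subtypes, or
any clinical class prior.  It exists so that every pipeline stage has
checkable ground truth; accuracies obtained on it say nothing about
clinical performance.

Exact event-count recovery is guaranteed (and tested) on a low-noise
configuration where amplitudes/durations clear the detection thresholds
by at least 2 bpm / 2 s; under full default noise, recovery of
threshold-grazing events is statistical, not exact.  The default
deceleration parameters (30 bpm / 90 s) were chosen during generator
design so the deep-deceleration clause (20 bpm for 30 s) is satisfied
with margin (supra-20-bpm duration ≈ 35 s).

## Numerical choices

- Engine dtype float32 (ample for these nets, 2× faster); feature
  computations in float64.
- All randomness flows through `numpy.random.Generator` seeds; derived
  seeds are reduced mod 2³¹.  Same seed ⇒ bit-identical records, weights
  and training curves on a single thread.
- Welch/filtering/t-test/AUC via SciPy/scikit-learn; CWT via PyWavelets;
  image resize via scikit-image; the spectrogram framing is hand-rolled
  (see above) to keep the Parseval contract exact.

## Problem sizes in the test suite

The acceptance-style checks run at desk scale, chosen to finish in
minutes on one CPU: 15 records/class for exact event recovery, 100
records/class for the STV class-ordering check, and 400 records/class
with 15 training epochs for the end-to-end learning check (held-out
accuracy of the combined model vs. a label-permutation null).  These sizes
are the package's own choices; they are large enough that the pass/fail
margins are not sampling flukes, and small enough to keep the whole suite
within a coffee break.

## Limitations

- The NumPy engine is single-threaded-deterministic but not fast; this is
  a reference implementation, not a training framework.
- The Mantel-style baseline is a simplified reconstruction; its window
  length bounds the duration of shallow excursions it can separate.
- ApEn parameters (m, r) and several protocol details are conventional
  defaults exposed as configuration, not claims about any particular
  clinical system.
- Synthetic results do not transfer to clinical data (see above).
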