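# Methods

This note documents the models, parameter choices and numerical decisions
behind `fingerdec`, and what the synthetic-data experiments do and do not
demonstrate.

## Decoding pipeline

The unit of analysis is a 1 s segment: movement segments at 4.5–5.5 s of
each 6 s trial (the first 500 ms after cue onset are treated as movement
preparation and excluded) and rest segments at 2.5–3.5 s (middle of
fixation). Windows are half-open `[start, end)` with 0-based indexing, so
1 s at 250 Hz is exactly 250 samples and the movement window starts at
sample 1125 of the epoch.

**Filtering.** High-pass (0.3 Hz) and band-stop (60 ± 0.3 Hz) order-4
Butterworth designs are applied with exactly zero phase by multiplying the
signal's spectrum with the design's squared magnitude response
`|H(f)|²`. This is the steady-state equivalent of forward–backward
(filtfilt) application, chosen because time-domain forward–backward
filtering of a Q≈100 notch rings at the record boundaries (measured
residual of 5–7% RMS on a pure 60 Hz tone), while the frequency-domain
application leaves ~1e-13. The cost is circular boundary semantics, which
is immaterial for minutes-long continuous records. Filters and the common
average reference are linear, so their order does not matter (verified to
1e-8).

**CAR.** Computed over *all* recorded channels, not only the decoding
subset; it makes the original recording reference immaterial up to a
common term.

**Periodogram.** One Hann-tapered DFT per segment and channel,
`P = |DFT(V·H)|²/T`, `T = 250`. The DC bin is dropped and bins 1..125
(1 Hz resolution at 250 Hz) are reported; the bin-to-Hz offset is stored
in `SpectralSet.meta`. No Welch averaging or multitapering is used — the
single-taper periodogram *is* the feature definition, and its per-bin
χ²₂ sampling noise is part of the method (see "Variance concentration"
below). The 60 Hz notched region is left in the spectrum.

**Normalization.** `P̃ = ln P − ln(mean over segments of P)`, per channel
and frequency, with movement and rest segments pooled in the mean. A
floor of 1e-12 µV²/Hz is applied before the logarithm (the log-ratio is
undefined at zero power). The reference mean is stored and re-applied to
held-out data, never re-estimated from it.

**Spectral PCA.** The second-moment matrix `C = Σ P̃ P̃ᵀ` (not
mean-centered — the normalization already removes the log-mean spectrum)
is eigendecomposed with a symmetric solver. By default every (channel,
segment) pair over the selected channels is one observation, yielding a
single shared basis per fit; a per-channel mode returns one basis per
channel. The per-channel mean reference keeps channel-specific spectral
shape out of the pooled decomposition. Eigenvectors are unit norm, sorted
by descending eigenvalue, signs fixed so each component's mean over
frequency is nonnegative (the broadband component then plots flat and
positive). Ties/degenerate eigenvalues are left in solver order.

**Decoding protocol.** 30 stratified random splits, 80% train / 20% test
within each finger (64/16 of 80 trials). Per permutation, the
normalization reference and the PCA basis are refitted on the training
movement + rest segments only; rest segments never enter the classifier.
Features are standardized per column with training statistics, then an
RBF-kernel SVM (C = 1, γ = 1/n_features, one-vs-one voting) is trained
per feature kind on identical splits, so comparisons between kinds are
paired. The SVM hyperparameters are library defaults; an optional inner
5-fold grid search on the training set is provided but off by default.
Band-power features are per-bin (channel × integer bin, alpha 8–12 Hz
inclusive = 5 bins, beta 13–30 Hz = 18 bins) from the raw PSD; a summed
per-band and a normalized-PSD variant exist as options. Temporal features
take every 10th sample of the segment (plain decimation starting at
sample 0, no anti-alias filter) — 25 values per channel.

**Statistics.** Accuracies are compared to the guess level (1/K derived
from the label set, 20% for five fingers) with a two-sided one-sample
t-test, and between kinds with paired two-sided t-tests; a zero numerator
is reported as t = 0, p = 1. Raw p-values are reported; Holm-adjusted
columns are emitted as a labelled extension. The default unit of analysis
is per-session means when several sessions are supplied; for
single-session runs permutation-level values are used and flagged, with
the caveat that permutation-level degrees of freedom are optimistic
(splits share trials).

## Synthetic sessions

The generator emulates the protocol's statistics: 250 Hz, 6 s trials,
80 trials per finger (400 trials, ~40 min), a region-tagged schematic
montage (default 64 channels; the decoding subset of ~30–40 channels
covers motor, parietal and posterior-frontal regions). Per channel the
signal is a sum of

* 1/f^x Gaussian background (x = 1, σ = 8 µV) with a per-trial lognormal
  global scale (ln-sd 0.3) shared by the whole trial — slow
  arousal/impedance drift, deliberately identical in the movement and
  rest windows;
* narrowband alpha (8–12 Hz) and beta (13–30 Hz) rhythms built by
  band-pass filtering white noise (realistic peak widths), scaled by
  region (posterior-dominant alpha: 6 µV parietal, 4 µV motor; beta 3 µV
  motor) with per-trial amplitude waxing/waning (ln-sd 0.6 / 0.5);
* a stationary white floor (2 µV);
* during the movement window, ramping in over the first 0.5 s of the cue:
  an added white component of variance `(gain − 1)·w[f,c]` times the
  floor variance (broadband power increase, default gain 2.0 at the
  somatotopic peak), and multiplicative alpha/beta attenuation on
  motor-region channels of depth `d·(0.4 + 0.6·ŵ[f,c])` (defaults
  d_alpha = 0.5, d_beta = 0.35 — fractional power reductions typical of
  movement ERD);
* optional common 60 Hz line noise (off by default).

`w[f,c]` are somatotopic weights: Gaussian bumps (σ = 0.18 of the strip
length) along the contralateral motor strip, one per finger, adjacent
bumps overlapping ≈0.54 — so misclassifications should fall on
neighbouring fingers — with attenuated copies on parietal (×0.45) and
ipsilateral motor (×0.15) channels. Effect sizes are calibration choices
on realism grounds, not measured values; ground truth is returned for
recovery tests. With all effect parameters zeroed the movement and rest
windows are statistically identical, which the null tests exploit.

Not emulated: volume conduction and channel-to-channel correlation of
the background, slow movement-related cortical potentials (hence
`temporal` features decode at chance on synthetic data, unlike on real
EEG where evoked waveforms carry class information), ocular/muscle
artifacts, and electrode drift within a trial. Passing tests therefore
show the pipeline recovers planted spectral/spatial structure and is
calibrated under the null — not that real-EEG accuracy levels are
reproduced.

## Variance concentration of the spectral basis

On default-effect sessions the first three spectral PCs capture ≈43% of
the total second-moment trace. This number has a hard ceiling well below
100%: each periodogram bin of a Gaussian-process signal is ~exponentially
distributed, so `ln P` carries an irreducible variance of π²/6 ≈ 1.645
per bin, independent across the 125 bins. That contributes ≈206 of
incoherent trace mass per observation, spread over ~122 eigendirections,
regardless of effect sizes. The coherent directions (global log-amplitude
scale plus the mean offset left by the log-of-mean normalization, the
alpha/beta amplitude direction, and the movement broadband/ERD offsets)
would need a combined mass of ~1850 — per-bin log-power swings of ~3.8
natural-log units, i.e. trial-to-trial power fluctuating by a factor of
~45 — for the top three components to reach 90%. Under physiologically
plausible amplitude variability the expected share is 30–50%; a
pure-noise session already gives ~21%. Higher shares require smoothed or
averaged spectral estimates, which this feature definition deliberately
does not use.

## Statistical calibration of the null check

The zero-effect acceptance check compares the 30-permutation mean
accuracy to 20% within 3 binomial standard errors. The SE is computed
over the **400 distinct trials** of the session, not over the 30 × 80
test predictions: permutations re-predict the same trials, so the 2400
predictions are correlated (measured across-session SD of the
permutation mean ≈ 0.012–0.015, between the 2400-draw value 0.008 and
the fully-correlated 400-trial bound 0.02). Cross-validated accuracy
under the null is also known to be slightly pessimistic in finite
samples; the measured grand mean over independent null sessions is
0.199.

## Problem sizes used in the test suite

Unit tests run on 16-channel sessions with 10–25 trials per finger;
the end-to-end null-calibration, structure-recovery and acceptance runs
use full-size sessions (64 channels, 80 trials per finger, 30
permutations). The type-I-error check of the guess-level t-test uses 500
replications of 30 binomial chance-level accuracies, exercising the test
machinery directly rather than repeating the full pipeline.

## Known limitations

* EDF export is not provided (no writer backend among the supported
  dependencies); sessions are written as delimited long-format tables
  with JSON sidecars or compact `.npz`. EDF reading is available via the
  optional `mne` extra.
* Component-based artifact removal is an identity hook unless an
  externally derived cleaning matrix is supplied; manual component
  selection is out of scope.
* The generator's effect parameters are synthetic calibration choices;
  absolute decoding accuracies on synthetic sessions should not be read
  as predictions for real EEG.
* Per-channel PCA mode returns independent bases whose component ranks
  need not correspond across channels.
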