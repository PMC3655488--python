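# fingerdec

Decoding **individual finger movements of one hand from noninvasive EEG**,
and comparing the movement-related features that make such decoding
possible. The package is aimed at BCI researchers who want a transparent,
fully testable implementation of the spectral-PCA feature pipeline next to
the classical alternatives (band powers, raw temporal amplitudes), plus a
synthetic session generator with known ground truth for validating every
stage.

## The method

A session consists of 6 s trials (2 s blank rest, 2 s fixation, 2 s cued
movement of one of five fingers), sampled at 250 Hz on a dense EEG net.
After 0.3 Hz high-pass and 60 Hz notch filtering, each channel *n* is
re-referenced to the common average,

$$V_{CAR}(n,t) = V(n,t) - \tfrac{1}{N}\sum_{i=1}^{N} V(i,t),$$

and 1 s movement (4.5–5.5 s) and rest (2.5–3.5 s) segments are cut from
each trial. Per segment *m* and channel, a single Hann-tapered periodogram
gives the power spectrum $P_n(f,m)$ on integer bins $f = 1..125$ Hz
($T = 250$ samples). Because EEG power follows a power law, spectra are
normalized as a log ratio to the mean spectrum over segments,

$$\tilde P_n(f,m) = \ln P_n(f,m) - \ln\Big(\tfrac{1}{M}\sum_{p=1}^{M} P_n(f,p)\Big),$$

and the second-moment matrix
$C(f,f') = \sum_{m} \tilde P(f,m)\,\tilde P(f',m)$ — pooling (channel,
segment) observations over the selected channels — is eigendecomposed.
The eigenvectors are **spectral principal components**: the first is flat
and positive (a broadband power-modulation feature), the second peaks in
the alpha/beta bands (the ERD phenomenon). Projection coefficients of
each segment's spectrum on chosen PCs are the decoding features.

Six feature kinds are compared under one protocol: `pc1`, `pc2`, `pc123`
(projections), `alpha` (8–12 Hz bins), `beta` (13–30 Hz bins) and
`temporal` (segments decimated to 25 Hz). For each of 30 stratified
random 80/20 splits, the normalization reference and PCA basis are fitted
on the training set only, and an RBF-kernel SVM (one-vs-one) is trained
and tested per kind on identical splits. Accuracies are compared against
the 20% guess level (one-sample t-test) and pairwise between kinds
(paired t-tests); confusion matrices expose the structure of errors.

## Worked example

```python
import fingerdec as fd

montage = fd.make_montage(32, seed=0)
cfg = fd.SimulationConfig(n_channels=32, n_trials_per_finger=40, seed=0)
rec, truth = fd.simulate_session(cfg, montage)
movement, rest = fd.preprocess_recording(rec)

_, basis = fd.session_spectral_basis(movement, rest, channels=montage.selected_indices)
print(f"variance captured by PC1-3: {100 * fd.variance_explained(basis, 3):.1f}%")

results = fd.run_evaluation(movement, rest, channels=montage.selected_indices,
                            config=fd.EvalConfig(n_permutations=10, seed=0))
report = fd.summarize(results, unit="permutation")
for kind in fd.FEATURE_KINDS:
    print(f"{kind:9s} {100*report.mean[kind]:5.1f}% +- {100*report.sd[kind]:4.1f}  "
          f"p vs 20% guess: {report.p_vs_guess[kind]:.2e}")
```

prints (half-size session: 32 channels, 40 trials per finger, 10 splits):

```
variance captured by PC1-3: 43.2%
pc1        27.7% +-  5.3  p vs 20% guess: 1.29e-03
pc2        29.5% +-  6.7  p vs 20% guess: 1.60e-03
pc123      34.5% +-  6.2  p vs 20% guess: 4.19e-05
alpha      24.3% +-  4.4  p vs 20% guess: 1.40e-02
beta       23.2% +-  5.0  p vs 20% guess: 7.03e-02
temporal   21.2% +-  4.1  p vs 20% guess: 3.63e-01
```

Combined spectral-PC projections (`pc123`) decode the five fingers well
above the 20% guess level and beat single-band powers, and the confusion
matrix concentrates errors on anatomically neighbouring fingers
(adjacent off-diagonal rate 0.242 vs 0.111 elsewhere in this run) — the
qualitative signatures the pipeline is designed to expose. Exact accuracy
levels depend on the synthetic effect sizes; see `docs/methods.md`.

The same pipeline runs from the shell:

```sh
fingerdec simulate --out session.npz --seed 1
fingerdec preprocess --in session.npz --out segments/
fingerdec decode --segments segments/ --out results.json
fingerdec report --results results.json --out report/
```

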