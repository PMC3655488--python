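"""Spectral PCA chain: periodogram, log-ratio normalization, eigenbasis.

The periodogram and the second-moment eigendecomposition are checked
against independent brute-force implementations (direct DFT sums and
dense nested-loop second moments).
"""

import numpy as np
import pytest

import fingerdec as fd
from fingerdec.spectral import SpectralSet, fit_spectral_pca, variance_explained

from conftest import make_segments

T = 250
FS = 250.0


def oracle_psd(x: np.ndarray) -> np.ndarray:
    """Direct DFT sum of the Hann-windowed segment, bins 1..125 Hz."""
    t = np.arange(T)
    h = 0.5 * (1.0 - np.cos(2 * np.pi * t / T))
    out = np.empty(T // 2)
    for f in range(1, T // 2 + 1):
        out[f - 1] = np.abs(np.sum(x * h * np.exp(1j * 2 * np.pi * f * t / T))) ** 2 / T
    return out


def oracle_second_moment(obs: np.ndarray) -> np.ndarray:
    n_bins = obs.shape[1]
    c = np.zeros((n_bins, n_bins))
    for row in obs:
        for i in range(n_bins):
            for j in range(n_bins):
                c[i, j] += row[i] * row[j]
    return c


def _norm_set(psd: np.ndarray, freqs=None) -> SpectralSet:
    """Wrap pre-normalized values in a SpectralSet for basis fitting."""
    psd = np.asarray(psd, dtype=float)
    freqs = np.arange(1, psd.shape[-1] + 1) if freqs is None else freqs
    return SpectralSet(
        psd=psd,
        freqs=np.asarray(freqs, dtype=float),
        labels=np.array(["thumb"] * psd.shape[0]),
        fs=FS,
        normalized=True,
    )


class TestPeriodogram:
    def test_zero_signal_gives_zero_psd(self):
        seg = make_segments(np.zeros((2, 1, T)), ["thumb", "index"])
        assert np.all(fd.compute_psd(seg).psd == 0)

    def test_matches_direct_dft(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 2, T))
        seg = make_segments(x, ["thumb", "index", "middle"])
        psd = fd.compute_psd(seg).psd
        for m in range(3):
            for c in range(2):
                ref = oracle_psd(x[m, c])
                np.testing.assert_allclose(psd[m, c], ref, rtol=1e-8, atol=1e-12)

    def test_10hz_cosine_peaks_at_10hz(self):
        t = np.arange(T) / FS
        seg = make_segments(np.cos(2 * np.pi * 10 * t)[None, None, :], ["thumb"])
        spec = fd.compute_psd(seg)
        p = spec.psd[0, 0]
        i10 = np.argmin(np.abs(spec.freqs - 10.0))
        i30 = np.argmin(np.abs(spec.freqs - 30.0))
        assert np.argmax(p) == i10
        assert p[i10] >= 100 * p[i30]

    def test_parseval_on_two_sided_spectrum(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(T)
        t = np.arange(T)
        h = 0.5 * (1.0 - np.cos(2 * np.pi * t / T))
        full = np.abs(np.fft.fft(x * h)) ** 2 / T
        energy = np.sum((x * h) ** 2)
        assert abs(full.sum() - energy) / energy < 1e-8

    def test_wrong_segment_length_rejected(self):
        seg = make_segments(np.zeros((1, 1, 200)), ["thumb"])
        with pytest.raises(ValueError):
            fd.compute_psd(seg)


class TestNormalization:
    def test_identical_segments_normalize_to_zero(self):
        psd = np.tile(np.linspace(1, 5, 10), (4, 2, 1))
        spec = SpectralSet(psd=psd, freqs=np.arange(1, 11.0), labels=np.array(["a"] * 4), fs=FS)
        out = fd.normalize_psd(spec)
        assert np.abs(out.psd).max() < 1e-12

    def test_two_segment_closed_form(self):
        psd = np.array([2.0, 8.0]).reshape(2, 1, 1)
        spec = SpectralSet(psd=psd, freqs=np.array([1.0]), labels=np.array(["a", "b"]), fs=FS)
        out = fd.normalize_psd(spec)
        np.testing.assert_allclose(out.psd[:, 0, 0], [np.log(2 / 5), np.log(8 / 5)])

    def test_mean_of_exp_identity(self):
        rng = np.random.default_rng(2)
        psd = rng.exponential(size=(20, 3, 15))
        spec = SpectralSet(psd=psd, freqs=np.arange(1, 16.0), labels=np.array(["a"] * 20), fs=FS)
        out = fd.normalize_psd(spec)
        assert np.abs(np.exp(out.psd).mean(axis=0) - 1.0).max() < 1e-9

    def test_stored_reference_is_reusable(self):
        rng = np.random.default_rng(3)
        train = rng.exponential(size=(10, 2, 5))
        test = rng.exponential(size=(4, 2, 5))
        freqs = np.arange(1, 6.0)
        spec_tr = SpectralSet(psd=train, freqs=freqs, labels=np.array(["a"] * 10), fs=FS)
        norm_tr = fd.normalize_psd(spec_tr)
        spec_te = SpectralSet(psd=test, freqs=freqs, labels=np.array(["a"] * 4), fs=FS)
        norm_te = fd.normalize_psd(spec_te, reference=norm_tr.norm_reference)
        np.testing.assert_allclose(norm_te.psd, np.log(test) - np.log(train.mean(axis=0)))

    def test_double_normalization_rejected(self):
        spec = _norm_set(np.zeros((2, 1, 3)))
        with pytest.raises(ValueError):
            fd.normalize_psd(spec)


class TestSpectralBasis:
    def test_rank_one_structure_recovered(self):
        rng = np.random.default_rng(4)
        u = rng.standard_normal(8)
        u /= np.linalg.norm(u)
        a = rng.standard_normal(12)
        spec = _norm_set(np.outer(a, u)[:, None, :])
        basis = fit_spectral_pca(spec)
        cosang = abs(basis.components[0] @ u)
        assert abs(cosang - 1.0) < 1e-8
        np.testing.assert_allclose(basis.eigenvalues[0], (a**2).sum(), rtol=1e-10)
        assert basis.eigenvalues[1:].max() < 1e-10 * basis.eigenvalues[0]
        assert variance_explained(basis, 1) > 1 - 1e-8

    def test_two_bin_toy_eigensystem(self):
        obs = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        spec = _norm_set(obs[:, None, :])
        basis = fit_spectral_pca(spec)
        np.testing.assert_allclose(basis.eigenvalues, [3.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(basis.components[0]), np.full(2, 1 / np.sqrt(2)))
        assert variance_explained(basis, 1) == pytest.approx(0.75)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        obs = rng.standard_normal((10, 6))
        spec = _norm_set(obs[:, None, :])
        basis = fit_spectral_pca(spec)
        c_ref = oracle_second_moment(obs)
        eigval_ref, eigvec_ref = np.linalg.eigh(c_ref)
        order = np.argsort(eigval_ref)[::-1]
        np.testing.assert_allclose(basis.eigenvalues, eigval_ref[order], rtol=1e-8)
        for k in range(6):
            cosang = abs(basis.components[k] @ eigvec_ref[:, order[k]])
            assert abs(cosang - 1.0) < 1e-8

    def test_orthonormal_sorted_and_reconstructs(self):
        rng = np.random.default_rng(6)
        spec = _norm_set(rng.standard_normal((30, 2, 12)))
        basis = fit_spectral_pca(spec)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(12), atol=1e-8)
        assert np.all(np.diff(basis.eigenvalues) <= 1e-12)
        assert basis.eigenvalues.min() >= -1e-10
        # sign convention: mean over frequency nonnegative
        assert np.all(basis.components.mean(axis=1) >= -1e-12)
        obs = spec.psd.reshape(-1, 12)
        c = obs.T @ obs
        recon = (basis.components.T * basis.eigenvalues) @ basis.components
        assert np.linalg.norm(recon - c) / np.linalg.norm(c) < 1e-8

    def test_per_channel_mode_gives_one_basis_each(self):
        rng = np.random.default_rng(7)
        spec = _norm_set(rng.standard_normal((20, 3, 6)))
        bases = fit_spectral_pca(spec, pooling="per-channel")
        assert len(bases) == 3
        for b in bases:
            np.testing.assert_allclose(b.components @ b.components.T, np.eye(6), atol=1e-8)

    def test_requires_normalized_input_and_enough_observations(self):
        raw = SpectralSet(
            psd=np.ones((4, 1, 3)), freqs=np.arange(1, 4.0),
            labels=np.array(["a"] * 4), fs=FS,
        )
        with pytest.raises(ValueError):
            fit_spectral_pca(raw)
        with pytest.raises(ValueError):
            fit_spectral_pca(_norm_set(np.ones((1, 1, 3))))


class TestProjection:
    def test_basis_vector_projects_to_unit_coefficient(self):
        rng = np.random.default_rng(8)
        spec = _norm_set(rng.standard_normal((10, 1, 6)))
        basis = fit_spectral_pca(spec)
        probe = _norm_set(basis.components[0][None, None, :])
        proj = fd.project_segments(probe, basis, pc_indices=range(1, 7))
        coeff = proj.coefficients[0, 0]
        np.testing.assert_allclose(coeff[0], 1.0, atol=1e-10)
        assert np.abs(coeff[1:]).max() < 1e-10

    def test_zero_spectra_project_to_zero(self):
        spec = _norm_set(np.random.default_rng(9).standard_normal((5, 1, 4)))
        basis = fit_spectral_pca(spec)
        zero = _norm_set(np.zeros((2, 1, 4)))
        proj = fd.project_segments(zero, basis, pc_indices=(1, 2))
        assert np.all(proj.coefficients == 0)

    def test_full_rank_projection_reconstructs(self):
        rng = np.random.default_rng(10)
        spec = _norm_set(rng.standard_normal((15, 2, 5)))
        basis = fit_spectral_pca(spec)
        proj = fd.project_segments(spec, basis, pc_indices=range(1, 6))
        recon = np.einsum("mnk,kf->mnf", proj.coefficients, basis.components)
        np.testing.assert_allclose(recon, spec.psd, atol=1e-8)

    def test_out_of_range_pcs_rejected(self):
        spec = _norm_set(np.ones((3, 1, 4)) * np.arange(1, 4)[:, None, None])
        basis = fit_spectral_pca(spec)
        with pytest.raises(ValueError):
            fd.project_segments(spec, basis, pc_indices=(5,))
        with pytest.raises(ValueError):
            variance_explained(basis, 0)
        with pytest.raises(ValueError):
            variance_explained(basis, 9)


def test_variance_explained_complete_basis_is_one():
    rng = np.random.default_rng(11)
    spec = _norm_set(rng.standard_normal((20, 1, 7)))
    basis = fit_spectral_pca(spec)
    assert variance_explained(basis, 7) == pytest.approx(1.0)
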