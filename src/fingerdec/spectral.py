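"""Spectral PCA of EEG power spectra.

The feature-extraction chain:

1. For each 1 s segment and channel, a single Hann-tapered periodogram

       P_n(f, m) = (1/T) | sum_t V(n, t, m) H(t) e^{i 2π (f-1) t / T} |^2

   with T = 250 samples at fs = 250 Hz, reported on integer bins
   f = 1..125 Hz (the DC bin is dropped; bin f sits at (f-1)·fs/T relative
   to the complex exponential above, i.e. 1 Hz resolution).

2. Log-ratio normalization against the mean spectrum over segments,

       P~_n(f, m) = ln P_n(f, m) - ln( (1/M) Σ_p P_n(f, p) ),

   computed per channel and frequency. EEG power follows a power law, so
   this puts all frequencies on a comparable scale; the reference mean is
   stored so held-out data can be normalized without touching its own
   statistics.

3. The second-moment matrix of the normalized spectra,

       C(f, f') = Σ_obs P~(f, obs) P~(f', obs),

   is eigendecomposed. Observations are, by default, all (channel,
   segment) pairs over the selected channels ("pooled"), yielding one
   shared spectral basis; a per-channel mode is available. Eigenvectors
   (spectral PCs) are unit norm, sorted by descending eigenvalue, with the
   sign fixed so each PC's mean over frequency is nonnegative (the leading
   broadband PC then plots as flat and positive).

4. Segments are projected onto chosen PCs; the projection coefficients
   per channel are the decoding features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .preprocess import SegmentSet

PSD_FLOOR = 1e-12  # µV²/Hz; the log-normalization is undefined at zero power


@dataclass
class SpectralSet:
    """Per-segment, per-channel power spectra on a fixed integer-Hz axis."""

    psd: np.ndarray  # segments x channels x freq-bins
    freqs: np.ndarray  # Hz, 1..125 for fs=250, T=250
    labels: np.ndarray
    fs: float
    normalized: bool = False
    norm_reference: Optional[np.ndarray] = None  # channels x freq-bins
    source_trial: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return self.psd.shape[0]

    @property
    def n_channels(self) -> int:
        return self.psd.shape[1]


@dataclass
class SpectralBasis:
    """Ordered spectral principal components fitted on a training set."""

    components: np.ndarray  # K x freq-bins, rows unit norm
    eigenvalues: np.ndarray  # K, nonincreasing, >= 0 (tiny negatives clipped)
    freqs: np.ndarray
    fit_meta: dict = field(default_factory=dict)
    sign_flipped: Optional[np.ndarray] = None

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class ProjectionFeatures:
    """Projection coefficients, segments x channels x requested PCs."""

    coefficients: np.ndarray
    pc_indices: tuple[int, ...]  # 1-based ranks
    channel_subset: np.ndarray


def compute_psd(seg: SegmentSet, T: int = 250) -> SpectralSet:
    """Single Hann-tapered periodogram per segment and channel.

    Deterministic; returns bins 1..T/2 (DC dropped), in µV²/Hz-like units
    (|DFT|²/T).
    """
    if seg.data.shape[-1] != T:
        raise ValueError(f"segment length {seg.data.shape[-1]} != window length {T}")
    t = np.arange(T)
    window = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / T))  # periodic Hann
    spec = np.fft.rfft(seg.data * window, axis=-1)
    psd = (np.abs(spec) ** 2) / T
    n_bins = T // 2
    freqs = np.arange(1, n_bins + 1) * seg.fs / T
    return SpectralSet(
        psd=psd[..., 1 : n_bins + 1],
        freqs=freqs,
        labels=np.asarray(seg.labels),
        fs=seg.fs,
        normalized=False,
        source_trial=seg.source_trial,
        meta={"window": "hann", "T": T, "bin_offset_hz": float(seg.fs / T)},
    )


def normalize_psd(
    spec: SpectralSet,
    reference: Optional[np.ndarray] = None,
    floor: float = PSD_FLOOR,
) -> SpectralSet:
    """Log-ratio normalization against the mean spectrum over segments.

    If ``reference`` (channels x bins, e.g. stored from a training set) is
    given it is used instead of the input's own mean, so held-out data
    never contributes to the normalizer.
    """
    if spec.normalized:
        raise ValueError("input is already normalized")
    psd = np.maximum(spec.psd, floor)
    if reference is None:
        reference = psd.mean(axis=0)  # per channel, per frequency
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != spec.psd.shape[1:]:
            raise ValueError("reference must be channels x freq-bins")
    if np.any(reference <= 0):
        raise ValueError("nonpositive reference PSD after flooring")
    out = np.log(psd) - np.log(reference)[None, :, :]
    return replace(spec, psd=out, normalized=True, norm_reference=reference)


def fit_spectral_pca(
    spec: SpectralSet,
    pooling: str = "pooled-channels",
    channels: Optional[Sequence[int]] = None,
):
    """Eigendecompose the second-moment matrix of normalized spectra.

    ``pooling="pooled-channels"`` (default) treats every (channel, segment)
    pair over ``channels`` as one observation and returns a single shared
    :class:`SpectralBasis`; ``pooling="per-channel"`` returns a list with
    one basis per channel.
    """
    if not spec.normalized:
        raise ValueError("fit requires a normalized SpectralSet")
    if channels is None:
        channels = np.arange(spec.n_channels)
    channels = np.asarray(channels)
    data = spec.psd[:, channels, :]  # m x n x F

    if pooling == "pooled-channels":
        obs = data.reshape(-1, data.shape[-1])
        return _fit_basis(obs, spec.freqs, {"pooling": pooling, "channels": channels.tolist()})
    if pooling == "per-channel":
        return [
            _fit_basis(
                data[:, j, :],
                spec.freqs,
                {"pooling": pooling, "channel": int(channels[j])},
            )
            for j in range(data.shape[1])
        ]
    raise ValueError(f"unknown pooling mode {pooling!r}")


def _fit_basis(obs: np.ndarray, freqs: np.ndarray, fit_meta: dict) -> SpectralBasis:
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 observations to fit a spectral basis")
    c = obs.T @ obs  # second moment, not mean-centered
    c = 0.5 * (c + c.T)  # enforce exact symmetry
    eigval, eigvec = np.linalg.eigh(c)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order].T  # rows = components
    flip = eigvec.mean(axis=1) < 0
    eigvec[flip] *= -1.0
    meta = dict(fit_meta)
    meta["n_observations"] = int(obs.shape[0])
    return SpectralBasis(
        components=eigvec,
        eigenvalues=eigval,
        freqs=np.asarray(freqs),
        fit_meta=meta,
        sign_flipped=flip,
    )


def project_segments(
    spec: SpectralSet,
    basis: SpectralBasis,
    pc_indices: Sequence[int] = (1, 2, 3),
    channels: Optional[Sequence[int]] = None,
) -> ProjectionFeatures:
    """Project normalized spectra onto chosen PCs (1-based ranks)."""
    if not spec.normalized:
        raise ValueError("projection requires a normalized SpectralSet")
    if len(basis.freqs) != spec.psd.shape[-1]:
        raise ValueError("basis frequency axis does not match the spectra")
    pc_indices = tuple(int(k) for k in pc_indices)
    if any(k < 1 or k > basis.n_components for k in pc_indices):
        raise ValueError(f"pc_indices {pc_indices} out of range 1..{basis.n_components}")
    if channels is None:
        channels = np.arange(spec.n_channels)
    channels = np.asarray(channels)
    comps = basis.components[[k - 1 for k in pc_indices], :]  # K' x F
    coeff = np.einsum("mnf,kf->mnk", spec.psd[:, channels, :], comps)
    return ProjectionFeatures(coefficients=coeff, pc_indices=pc_indices, channel_subset=channels)


def variance_explained(basis: SpectralBasis, k: int) -> float:
    """Fraction of total spectral variance in the first k components."""
    if not 1 <= k <= basis.n_components:
        raise ValueError(f"k must lie in 1..{basis.n_components}")
    total = basis.eigenvalues.sum()
    return float(basis.eigenvalues[:k].sum() / total)


def session_spectral_basis(
    movement: SegmentSet,
    rest: SegmentSet,
    channels: Optional[Sequence[int]] = None,
    pooling: str = "pooled-channels",
    T: int = 250,
):
    """Fit the spectral basis of a whole session (movement + rest pooled).

    Convenience wrapper for descriptive analyses (PC profiles, variance
    concentration); the decoding protocol instead refits per training
    split. Returns ``(normalized SpectralSet, SpectralBasis)``.
    """
    spec_m = compute_psd(movement, T=T)
    spec_r = compute_psd(rest, T=T)
    pooled = SpectralSet(
        psd=np.concatenate([spec_m.psd, spec_r.psd], axis=0),
        freqs=spec_m.freqs,
        labels=np.concatenate([spec_m.labels, spec_r.labels]),
        fs=spec_m.fs,
        meta=dict(spec_m.meta),
    )
    norm = normalize_psd(pooled)
    basis = fit_spectral_pca(norm, pooling=pooling, channels=channels)
    return norm, basis


def write_basis_table(basis: SpectralBasis, path, n_components: int = 10) -> None:
    """Write PC profiles (component x frequency) as a delimited table."""
    import pandas as pd

    k = min(n_components, basis.n_components)
    df = pd.DataFrame(
        basis.components[:k].T,
        index=pd.Index(basis.freqs, name="freq_hz"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    df.to_csv(path, float_format="%.8g")
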