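"""Comparison features: alpha/beta band powers and decimated temporal data.

These are built on exactly the same 1 s movement segments and channel
subset as the spectral-PCA projections, so the decoding comparison is
paired segment for segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .preprocess import REST_LABEL, SegmentSet
from .spectral import ProjectionFeatures, SpectralBasis, SpectralSet, project_segments

#: inclusive integer band edges in Hz
BANDS = {"alpha": (8, 12), "beta": (13, 30)}

FEATURE_KINDS = ("pc1", "pc2", "pc123", "alpha", "beta", "temporal")


@dataclass
class FeatureMatrix:
    """Segments x features, with per-column provenance."""

    values: np.ndarray
    labels: np.ndarray
    kind: str
    column_meta: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.labels):
            raise ValueError("values must be segments x features with one label per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def band_power(
    spec: SpectralSet,
    band: str | tuple[float, float],
    channels: Optional[Sequence[int]] = None,
    aggregate: bool = False,
    allow_normalized: bool = False,
) -> FeatureMatrix:
    """Per-bin spectral power features within one band.

    One column per (channel, integer frequency bin) inside the inclusive
    band (alpha: 8..12 Hz -> 5 bins/channel, beta: 13..30 Hz -> 18
    bins/channel), taken from the raw PSD. ``aggregate=True`` sums the
    bins into one column per channel instead.
    """
    if spec.normalized and not allow_normalized:
        raise ValueError("band powers are defined on the raw (non-normalized) PSD")
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if lo < spec.freqs.min() or hi > spec.freqs.max():
        raise ValueError(f"band {lo}-{hi} Hz outside the frequency axis")
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if channels is None:
        channels = np.arange(spec.n_channels)
    channels = np.asarray(channels)
    sub = spec.psd[:, channels, :][:, :, mask]  # m x n x bins
    name = band if isinstance(band, str) else f"{lo}-{hi}Hz"
    if aggregate:
        values = sub.sum(axis=2)
        meta = [(int(c), name) for c in channels]
    else:
        m = sub.shape[0]
        values = sub.reshape(m, -1)
        meta = [(int(c), float(f)) for c in channels for f in spec.freqs[mask]]
    return FeatureMatrix(values=values, labels=spec.labels, kind=name, column_meta=meta)


def temporal_downsample(
    seg: SegmentSet, factor: int = 10, channels: Optional[Sequence[int]] = None
) -> FeatureMatrix:
    """Plain decimation of segment amplitudes (no anti-alias filter).

    Keeps samples 0, factor, 2·factor, ...; a 250-sample segment at
    factor 10 yields 25 values per channel (a 25 Hz amplitude series).
    """
    n = seg.data.shape[-1]
    if n % factor != 0:
        raise ValueError(f"segment length {n} not divisible by factor {factor}")
    if channels is None:
        channels = np.arange(seg.n_channels)
    channels = np.asarray(channels)
    sub = seg.data[:, channels, ::factor]  # m x n x (len/factor)
    m, nch, k = sub.shape
    meta = [(int(c), int(s * factor)) for c in channels for s in range(k)]
    return FeatureMatrix(
        values=sub.reshape(m, -1), labels=seg.labels, kind="temporal", column_meta=meta
    )


def projection_features(
    proj: ProjectionFeatures, labels: np.ndarray, kind: str
) -> FeatureMatrix:
    m, nch, k = proj.coefficients.shape
    meta = [
        (int(c), f"PC{pc}") for c in proj.channel_subset for pc in proj.pc_indices
    ]
    return FeatureMatrix(
        values=proj.coefficients.reshape(m, -1), labels=labels, kind=kind, column_meta=meta
    )


_PC_SETS = {"pc1": (1,), "pc2": (2,), "pc123": (1, 2, 3)}


def assemble_features(
    kind: str,
    movement_spec: Optional[SpectralSet] = None,
    movement_norm: Optional[SpectralSet] = None,
    movement_segments: Optional[SegmentSet] = None,
    basis: Optional[SpectralBasis] = None,
    channels: Optional[Sequence[int]] = None,
) -> FeatureMatrix:
    """Build one of the six evaluated feature matrices on movement segments.

    * ``pc1`` / ``pc2`` / ``pc123``: projection coefficients (needs the
      normalized movement spectra and a fitted basis); columns are
      (channel x PC) flattened;
    * ``alpha`` / ``beta``: per-bin raw band powers (needs raw spectra);
    * ``temporal``: decimated amplitudes (needs the movement SegmentSet).
    """
    if kind in _PC_SETS:
        if movement_norm is None or basis is None:
            raise ValueError(f"kind {kind!r} needs normalized spectra and a basis")
        pcs = _PC_SETS[kind]
        if max(pcs) > basis.n_components:
            raise ValueError(f"kind {kind!r} needs {max(pcs)} components, basis has {basis.n_components}")
        _check_movement_only(movement_norm.labels)
        proj = project_segments(movement_norm, basis, pc_indices=pcs, channels=channels)
        return projection_features(proj, movement_norm.labels, kind)
    if kind in BANDS:
        if movement_spec is None:
            raise ValueError(f"kind {kind!r} needs raw spectra")
        _check_movement_only(movement_spec.labels)
        return band_power(movement_spec, kind, channels=channels)
    if kind == "temporal":
        if movement_segments is None:
            raise ValueError("kind 'temporal' needs the movement SegmentSet")
        _check_movement_only(np.asarray(movement_segments.labels))
        return temporal_downsample(movement_segments, channels=channels)
    raise ValueError(f"unknown feature kind {kind!r}; choose from {FEATURE_KINDS}")


def _check_movement_only(labels: np.ndarray) -> None:
    if np.any(labels == REST_LABEL):
        raise ValueError("feature matrices must contain movement segments only")


def write_feature_table(fm: FeatureMatrix, path) -> None:
    """Delimited table with a column_meta header row and a label sidecar."""
    import json

    import pandas as pd

    cols = ["|".join(str(p) for p in meta) for meta in fm.column_meta]
    pd.DataFrame(fm.values, columns=cols).to_csv(path, index=False, float_format="%.8g")
    sidecar = {"kind": fm.kind, "labels": [str(l) for l in fm.labels]}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh)
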