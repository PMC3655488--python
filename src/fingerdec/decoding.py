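"""Repeated random-split SVM decoding of individual finger movements.

Protocol: the movement segments are randomly split 30 times into 80%
training / 20% testing (stratified by finger). For every permutation, all
training-dependent feature machinery — the PSD normalization reference,
the spectral-PCA basis and the feature standardizer — is fitted on the
training set only and merely applied to the test set. A Gaussian-kernel
(RBF) support-vector machine with one-vs-one multiclass voting is trained
per feature kind on identical splits, so accuracies are paired across
kinds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_KINDS, FeatureMatrix, assemble_features
from .preprocess import FINGER_ORDER, SegmentSet
from .spectral import compute_psd, fit_spectral_pca, normalize_psd

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Stratified train/test index lists for each permutation."""

    train: list[np.ndarray]
    test: list[np.ndarray]
    n_permutations: int
    train_fraction: float
    seed: int


@dataclass
class DecodingResult:
    """Per-permutation accuracies and confusion counts for one feature kind."""

    feature_kind: str
    accuracies: np.ndarray  # (n_permutations,)
    confusions: np.ndarray  # (n_permutations, K, K), true x predicted
    class_order: tuple[str, ...] = FINGER_ORDER
    config: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)


@dataclass
class EvalConfig:
    """Knobs of the decoding protocol."""

    kinds: tuple[str, ...] = FEATURE_KINDS
    n_permutations: int = 30
    train_fraction: float = 0.8
    seed: int = 0
    svm_c: float = 1.0
    svm_gamma: str | float = "auto"  # 'auto' = 1 / n_features
    tune: bool = False  # inner 5-fold grid search on the training set
    pooling: str = "pooled-channels"
    psd_window: int = 250


def make_splits(
    labels: Sequence[str],
    n_permutations: int = 30,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Stratified random 80/20 splits, deterministic given the seed."""
    labels = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 trials: {bad.tolist()}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _ in range(n_permutations):
        tr, te = [], []
        for cls in classes:
            idx = rng.permutation(np.flatnonzero(labels == cls))
            n_train = int(round(train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            tr.append(idx[:n_train])
            te.append(idx[n_train:])
        train.append(np.sort(np.concatenate(tr)))
        test.append(np.sort(np.concatenate(te)))
    return SplitPlan(train, test, n_permutations, train_fraction, seed)


def _fit_classifier(
    x_train: np.ndarray,
    y_train: np.ndarray,
    c: float = 1.0,
    gamma: str | float = "auto",
    tune: bool = False,
):
    """Standardizer + RBF-SVM fitted on training rows only."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate training set: single class")
    scaler = StandardScaler().fit(x_train)
    xs = scaler.transform(x_train)
    if tune:
        grid = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", "auto", 0.001, 0.01]}
        search = GridSearchCV(SVC(kernel="rbf"), grid, cv=5)
        search.fit(xs, y_train)
        clf = search.best_estimator_
    else:
        clf = SVC(kernel="rbf", C=c, gamma=gamma).fit(xs, y_train)
    return scaler, clf


def train_and_test(
    features: FeatureMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    c: float = 1.0,
    gamma: str | float = "auto",
    tune: bool = False,
    class_order: Sequence[str] = FINGER_ORDER,
) -> tuple[float, np.ndarray]:
    """Train on the training rows, return (accuracy, confusion) on test rows.

    The confusion matrix is true x predicted in ``class_order``; accuracy
    equals its trace over its total by construction.
    """
    x, y = features.values, features.labels
    scaler, clf = _fit_classifier(x[train_idx], y[train_idx], c=c, gamma=gamma, tune=tune)
    pred = clf.predict(scaler.transform(x[test_idx]))
    conf = confusion_matrix(y[test_idx], pred, labels=list(class_order))
    acc = float(np.trace(conf) / conf.sum())
    return acc, conf


def fit_feature_state(
    movement: SegmentSet,
    rest: SegmentSet,
    train_idx: np.ndarray,
    channels: Optional[Sequence[int]] = None,
    pooling: str = "pooled-channels",
    psd_window: int = 250,
):
    """Fit all training-dependent spectral state for one permutation.

    Returns ``(norm_reference, basis)``: the per-channel mean PSD over the
    training movement + rest segments, and the spectral basis fitted on
    those same segments. Nothing outside ``train_idx`` is read — the
    leakage guarantee of the protocol.
    """
    spec_mov = compute_psd(movement, T=psd_window)
    spec_rest = compute_psd(rest, T=psd_window)
    train_psd = np.concatenate(
        [spec_mov.psd[train_idx], spec_rest.psd[train_idx]], axis=0
    )
    reference = np.maximum(train_psd, 1e-12).mean(axis=0)
    train_norm = np.log(np.maximum(train_psd, 1e-12)) - np.log(reference)[None]
    from .spectral import SpectralSet, _fit_basis  # local: avoid API clutter

    if channels is None:
        channels = np.arange(movement.n_channels)
    channels = np.asarray(channels)
    if pooling != "pooled-channels":
        raise ValueError("per-permutation refitting supports pooled-channels only")
    obs = train_norm[:, channels, :].reshape(-1, train_norm.shape[-1])
    basis = _fit_basis(obs, spec_mov.freqs, {"pooling": pooling, "channels": channels.tolist()})
    return reference, basis


def run_evaluation(
    movement: SegmentSet,
    rest: SegmentSet,
    channels: Optional[Sequence[int]] = None,
    config: Optional[EvalConfig] = None,
) -> dict[str, DecodingResult]:
    """Full decoding protocol: one DecodingResult per feature kind.

    For each permutation the Eq-normalization reference and spectral basis
    are refitted on the training movement + rest segments; all feature
    kinds are then trained and tested on identical splits.
    """
    config = config or EvalConfig()
    unknown = set(config.kinds) - set(FEATURE_KINDS)
    if unknown:
        raise ValueError(f"unknown feature kinds: {sorted(unknown)}")
    if channels is None:
        channels = np.arange(movement.n_channels)
    channels = np.asarray(channels)

    labels = np.asarray(movement.labels)
    plan = make_splits(labels, config.n_permutations, config.train_fraction, config.seed)

    # training-independent ingredients, computed once
    spec_mov = compute_psd(movement, T=config.psd_window)
    spec_rest = compute_psd(rest, T=config.psd_window)
    static_features: dict[str, FeatureMatrix] = {}
    for kind in config.kinds:
        if kind in ("alpha", "beta"):
            static_features[kind] = assemble_features(
                kind, movement_spec=spec_mov, channels=channels
            )
        elif kind == "temporal":
            static_features[kind] = assemble_features(
                kind, movement_segments=movement, channels=channels
            )

    n_classes = len(FINGER_ORDER)
    acc = {k: np.zeros(plan.n_permutations) for k in config.kinds}
    conf = {k: np.zeros((plan.n_permutations, n_classes, n_classes), dtype=int) for k in config.kinds}

    pc_kinds = [k for k in config.kinds if k.startswith("pc")]
    for p in range(plan.n_permutations):
        tr, te = plan.train[p], plan.test[p]
        per_perm: dict[str, FeatureMatrix] = dict(static_features)
        if pc_kinds:
            reference, basis = fit_feature_state(
                movement, rest, tr, channels=channels, pooling=config.pooling,
                psd_window=config.psd_window,
            )
            mov_norm = normalize_psd(spec_mov, reference=reference)
            for kind in pc_kinds:
                per_perm[kind] = assemble_features(
                    kind, movement_norm=mov_norm, basis=basis, channels=channels
                )
        for kind in config.kinds:
            try:
                a, cm = train_and_test(
                    per_perm[kind], tr, te,
                    c=config.svm_c, gamma=config.svm_gamma, tune=config.tune,
                )
            except Exception as err:
                raise RuntimeError(
                    f"decoding failed at permutation {p}, feature kind {kind!r}: {err}"
                ) from err
            acc[kind][p] = a
            conf[kind][p] = cm
            logger.info("perm %02d  %-8s accuracy %.3f", p, kind, a)

    snapshot = {
        "n_permutations": config.n_permutations,
        "train_fraction": config.train_fraction,
        "seed": config.seed,
        "svm_c": config.svm_c,
        "svm_gamma": config.svm_gamma,
        "pooling": config.pooling,
        "channels": channels.tolist(),
    }
    return {
        k: DecodingResult(
            feature_kind=k, accuracies=acc[k], confusions=conf[k], config=dict(snapshot)
        )
        for k in config.kinds
    }


def results_to_json(results: dict[str, DecodingResult]) -> dict:
    return {
        k: {
            "feature_kind": r.feature_kind,
            "accuracies": r.accuracies.tolist(),
            "confusions": r.confusions.tolist(),
            "class_order": list(r.class_order),
            "config": r.config,
        }
        for k, r in results.items()
    }


def results_from_json(d: dict) -> dict[str, DecodingResult]:
    return {
        k: DecodingResult(
            feature_kind=v["feature_kind"],
            accuracies=np.asarray(v["accuracies"]),
            confusions=np.asarray(v["confusions"], dtype=int),
            class_order=tuple(v["class_order"]),
            config=v.get("config", {}),
        )
        for k, v in d.items()
    }
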