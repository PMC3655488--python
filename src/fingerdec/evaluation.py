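"""Aggregate decoding results into accuracy summaries, t-tests and
confusion matrices.

Accuracies are compared against the chance level (1/K for a balanced
K-class problem, 20% for five fingers) with a two-sided one-sample t-test,
and between feature kinds with paired two-sided t-tests. The unit of
analysis is configurable: per-session mean accuracies (appropriate when
several sessions/subjects are available) or raw permutation-level
accuracies (a single session; degrees of freedom are then optimistic,
which the report labels explicitly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoding import DecodingResult


@dataclass
class StatReport:
    kinds: list[str]
    mean: dict[str, float]
    sd: dict[str, float]
    n_units: dict[str, int]
    guess_level: float
    t_vs_guess: dict[str, float]
    p_vs_guess: dict[str, float]
    p_vs_guess_holm: dict[str, float]  # extension: Holm-adjusted
    pairwise_p: pd.DataFrame
    pairwise_p_holm: pd.DataFrame  # extension: Holm-adjusted
    units_of_analysis: str = "permutation"
    extras: dict = field(default_factory=dict)


def _one_sample_t(values: np.ndarray, popmean: float) -> tuple[float, float]:
    """Two-sided one-sample t; a zero numerator yields t=0, p=1 exactly."""
    values = np.asarray(values, dtype=float)
    diff = values - popmean
    if np.allclose(diff.mean(), 0.0):
        return 0.0, 1.0
    if np.allclose(diff.std(ddof=1), 0.0):
        return float(np.inf) * np.sign(diff.mean()), 0.0
    res = stats.ttest_1samp(values, popmean)
    return float(res.statistic), float(res.pvalue)


def _paired_t(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    t, p = _one_sample_t(d, 0.0)
    return p


def _unit_values(
    res: DecodingResult | Sequence[DecodingResult], unit: str
) -> np.ndarray:
    if isinstance(res, DecodingResult):
        sessions = [res]
    else:
        sessions = list(res)
    if unit == "session-means":
        return np.array([s.accuracies.mean() for s in sessions])
    if unit == "permutation":
        return np.concatenate([s.accuracies for s in sessions])
    raise ValueError(f"unknown unit of analysis {unit!r}")


def summarize(
    results: Mapping[str, DecodingResult | Sequence[DecodingResult]],
    unit: str = "permutation",
    guess_level: float | None = None,
) -> StatReport:
    """Means/SDs per feature kind plus guess-level and pairwise t-tests."""
    if not results:
        raise ValueError("empty results")
    kinds = list(results)
    values = {k: _unit_values(results[k], unit) for k in kinds}
    for k, v in values.items():
        if len(v) < 2:
            raise ValueError(
                f"kind {k!r} has {len(v)} value(s) at unit {unit!r}; need >= 2"
            )
    if guess_level is None:
        first = results[kinds[0]]
        first = first if isinstance(first, DecodingResult) else first[0]
        guess_level = 1.0 / first.n_classes

    t_g, p_g = {}, {}
    for k in kinds:
        t_g[k], p_g[k] = _one_sample_t(values[k], guess_level)
    rejected = multipletests(list(p_g.values()), method="holm")[1]
    p_g_holm = dict(zip(kinds, (float(x) for x in rejected)))

    pair = pd.DataFrame(np.ones((len(kinds), len(kinds))), index=kinds, columns=kinds)
    for i, a in enumerate(kinds):
        for j, b in enumerate(kinds):
            if i < j:
                if len(values[a]) != len(values[b]):
                    raise ValueError("paired t-tests need equal-length accuracy vectors")
                pair.loc[a, b] = pair.loc[b, a] = _paired_t(values[a], values[b])
    # Holm correction over the upper-triangle family
    iu = np.triu_indices(len(kinds), k=1)
    raw = pair.values[iu]
    holm = pair.copy()
    if len(raw):
        adj = multipletests(raw, method="holm")[1]
        hv = holm.values
        hv[iu] = adj
        hv[(iu[1], iu[0])] = adj

    return StatReport(
        kinds=kinds,
        mean={k: float(values[k].mean()) for k in kinds},
        sd={k: float(values[k].std(ddof=1)) for k in kinds},
        n_units={k: int(len(values[k])) for k in kinds},
        guess_level=float(guess_level),
        t_vs_guess=t_g,
        p_vs_guess=p_g,
        p_vs_guess_holm=p_g_holm,
        pairwise_p=pair,
        pairwise_p_holm=holm,
        units_of_analysis=unit,
    )


def confusion_summary(
    results: Mapping[str, DecodingResult | Sequence[DecodingResult]],
) -> dict[str, dict[str, np.ndarray]]:
    """Sum confusion counts over permutations (and sessions) per kind.

    Returns, per kind, the aggregated counts (true x predicted) and a
    row-normalized version (rows sum to 1).
    """
    if not results:
        raise ValueError("empty results")
    out = {}
    for k, res in results.items():
        sessions = [res] if isinstance(res, DecodingResult) else list(res)
        counts = np.sum([s.confusions.sum(axis=0) for s in sessions], axis=0)
        rows = counts.sum(axis=1, keepdims=True)
        norm = counts / np.maximum(rows, 1)
        out[k] = {"counts": counts, "normalized": norm, "class_order": sessions[0].class_order}
    return out


def adjacent_confusion_share(confusion: np.ndarray) -> tuple[float, float]:
    """Mean off-diagonal mass on the super/sub diagonals vs elsewhere.

    Returns (mean mass per adjacent off-diagonal cell, mean mass per
    non-adjacent off-diagonal cell) of a row-normalized confusion matrix.
    Classes are assumed ordered anatomically (thumb..little).
    """
    k = confusion.shape[0]
    adj, far = [], []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            (adj if abs(i - j) == 1 else far).append(confusion[i, j])
    return float(np.mean(adj)), float(np.mean(far))


def render_report(
    report: StatReport,
    confusions: Mapping[str, dict],
    out_dir: str | Path,
) -> list[Path]:
    """Write the summary tables: accuracies, t-test grid, confusions + JSON.

    Deterministic: rerunning on the same inputs is byte-identical.
    """
    if not report.kinds or not confusions:
        raise ValueError("empty report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    acc = pd.DataFrame(
        {
            "kind": report.kinds,
            "n_units": [report.n_units[k] for k in report.kinds],
            "mean_accuracy": [report.mean[k] for k in report.kinds],
            "sd_accuracy": [report.sd[k] for k in report.kinds],
            "t_vs_guess": [report.t_vs_guess[k] for k in report.kinds],
            "p_vs_guess": [report.p_vs_guess[k] for k in report.kinds],
            "p_vs_guess_holm": [report.p_vs_guess_holm[k] for k in report.kinds],
        }
    )
    f_acc = out / "accuracy_summary.csv"
    acc.to_csv(f_acc, index=False, float_format="%.6g")

    grid = report.pairwise_p.copy()
    grid["guess_level"] = [report.p_vs_guess[k] for k in report.kinds]
    f_grid = out / "ttest_pvalues.csv"
    grid.to_csv(f_grid, float_format="%.6g")

    rows = []
    for k, d in confusions.items():
        order = list(d["class_order"])
        for kind_mat, name in ((d["counts"], "count"), (d["normalized"], "rate")):
            for i, true_lbl in enumerate(order):
                for j, pred_lbl in enumerate(order):
                    rows.append((k, name, true_lbl, pred_lbl, kind_mat[i, j]))
    f_conf = out / "confusion_matrices.csv"
    pd.DataFrame(
        rows, columns=["kind", "value_type", "true", "predicted", "value"]
    ).to_csv(f_conf, index=False, float_format="%.6g")

    f_json = out / "summary.json"
    payload = {
        "units_of_analysis": report.units_of_analysis,
        "guess_level": report.guess_level,
        "mean": report.mean,
        "sd": report.sd,
        "n_units": report.n_units,
        "t_vs_guess": report.t_vs_guess,
        "p_vs_guess": report.p_vs_guess,
        "p_vs_guess_holm": report.p_vs_guess_holm,
        "pairwise_p": report.pairwise_p.round(10).to_dict(),
        "pairwise_p_holm": report.pairwise_p_holm.round(10).to_dict(),
    }
    f_json.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return [f_acc, f_grid, f_conf, f_json]
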