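"""Clustering agreement metrics: accuracy under optimal label matching,
Rand index, and pairwise precision/recall/F1.

All three are invariant to relabeling of either input and are reported as
percentages in [0, 100].

* Accuracy matches predicted to true cluster labels with the Kuhn-Munkres
  (Hungarian) algorithm on the contingency table and counts agreements.
* The Rand index counts sample pairs treated consistently by both
  labelings: ``a`` pairs co-clustered in both, ``b`` pairs separated in
  both, out of C(N, 2).
* Pairwise F1 treats "co-clustered pair" as the positive class: TP pairs
  co-clustered in both labelings, FP only in the prediction, FN only in
  the truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MetricsReport",
    "clustering_accuracy",
    "rand_index",
    "pairwise_f1",
    "evaluate_clustering",
]


@dataclasses.dataclass
class MetricsReport:
    """Acc/RI/F1 (percent) with the matching and pair counts behind them."""

    acc: float
    ri: float
    f1: float
    precision: float
    recall: float
    matching: dict  # predicted label -> matched true label
    pair_counts: dict  # a, b, TP, FP, FN

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matching"] = {str(k): v for k, v in self.matching.items()}
        return d


def _check_pair(truth, pred, min_len: int = 1):
    t = np.asarray(truth).ravel()
    p = np.asarray(pred).ravel()
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.size} vs {p.size}")
    if t.size < min_len:
        raise ValueError(f"need at least {min_len} samples, got {t.size}")
    return t, p


def _contingency(truth: np.ndarray, pred: np.ndarray):
    t_vals, t_idx = np.unique(truth, return_inverse=True)
    p_vals, p_idx = np.unique(pred, return_inverse=True)
    table = np.zeros((p_vals.size, t_vals.size), dtype=np.int64)
    np.add.at(table, (p_idx, t_idx), 1)
    return table, p_vals, t_vals


def clustering_accuracy(truth, pred) -> tuple[float, dict]:
    """Accuracy (percent) under the optimal predicted-to-true label matching.

    Returns ``(acc, matching)`` where ``matching`` maps each matched
    predicted label to its assigned true label.
    """
    t, p = _check_pair(truth, pred, min_len=1)
    table, p_vals, t_vals = _contingency(t, p)
    rows, cols = linear_sum_assignment(-table)
    matched = int(table[rows, cols].sum())
    matching = {p_vals[r].item(): t_vals[c].item() for r, c in zip(rows, cols)}
    return 100.0 * matched / t.size, matching


def _pair_counts(truth: np.ndarray, pred: np.ndarray) -> dict:
    table, _, _ = _contingency(truth, pred)
    n = truth.size

    def c2(x):
        x = np.asarray(x, dtype=np.int64)
        return int((x * (x - 1) // 2).sum())

    tp = c2(table)  # co-clustered in both
    pred_pairs = c2(table.sum(axis=1))
    true_pairs = c2(table.sum(axis=0))
    total = n * (n - 1) // 2
    fp = pred_pairs - tp
    fn = true_pairs - tp
    b = total - pred_pairs - true_pairs + tp  # separated in both
    return {"a": tp, "b": b, "TP": tp, "FP": fp, "FN": fn, "total_pairs": total}


def rand_index(truth, pred) -> float:
    """Rand index in percent: (a + b) / C(N, 2) * 100."""
    t, p = _check_pair(truth, pred, min_len=2)
    pc = _pair_counts(t, p)
    return 100.0 * (pc["a"] + pc["b"]) / pc["total_pairs"]


def pairwise_f1(truth, pred) -> tuple[float, float, float]:
    """Pairwise (F1, precision, recall), each in percent.

    All three are 0 when TP = 0 (the degenerate all-singletons agreement).
    """
    t, p = _check_pair(truth, pred, min_len=2)
    pc = _pair_counts(t, p)
    tp, fp, fn = pc["TP"], pc["FP"], pc["FN"]
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return f1, precision, recall


def evaluate_clustering(truth, pred) -> MetricsReport:
    """All metrics in one report, sharing a single contingency pass."""
    t, p = _check_pair(truth, pred, min_len=2)
    acc, matching = clustering_accuracy(t, p)
    pc = _pair_counts(t, p)
    ri = 100.0 * (pc["a"] + pc["b"]) / pc["total_pairs"]
    f1, precision, recall = pairwise_f1(t, p)
    return MetricsReport(
        acc=acc,
        ri=ri,
        f1=f1,
        precision=precision,
        recall=recall,
        matching=matching,
        pair_counts={k: pc[k] for k in ("a", "b", "TP", "FP", "FN")},
    )
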