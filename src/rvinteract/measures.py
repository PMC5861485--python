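"""Evaluation measures for risk-model selection.

Pure functions shared by the collapsing, MDR and search layers: Shannon
entropy, information gain (mutual information between a phenotype and a
discrete genotype factor), balanced accuracy of a high/low risk
classification, and (weighted) cross-validation consistency.

All entropies use base-2 logarithms, so a balanced case-control phenotype
has entropy exactly 1 bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.special import xlogy

__all__ = [
    "ContingencySummary",
    "entropy",
    "information_gain",
    "balanced_accuracy",
    "cvc",
    "wcvc",
]


@dataclass(frozen=True)
class ContingencySummary:
    """Confusion counts of a binary risk classification.

    ``tp``/``fn`` count true cases predicted high/low risk; ``tn``/``fp``
    count true controls predicted low/high risk.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")

    @classmethod
    def from_predictions(cls, truth, predicted_high) -> "ContingencySummary":
        """Tabulate counts from a 0/1 truth vector and a boolean prediction."""
        t = np.asarray(truth).astype(bool)
        p = np.asarray(predicted_high).astype(bool)
        if t.shape != p.shape:
            raise ValueError("truth and prediction lengths differ")
        return cls(
            tp=int(np.sum(p & t)),
            fp=int(np.sum(p & ~t)),
            tn=int(np.sum(~p & ~t)),
            fn=int(np.sum(~p & t)),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def entropy(labels) -> float:
    """Shannon entropy (bits) of a discrete label vector.

    ``0 * log 0`` is taken as 0; an empty vector is an error.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-np.sum(xlogy(p, p)) / np.log(2.0))


def information_gain(phenotype, factor) -> float:
    """IG(T, g) = H(T) - H(T | g) in bits.

    ``phenotype`` and ``factor`` are equal-length discrete vectors. The
    result is non-negative (tiny negative rounding residue is clamped).
    """
    t = np.asarray(phenotype)
    g = np.asarray(factor)
    if t.shape != g.shape or t.ndim != 1:
        raise ValueError("phenotype and factor must be equal-length 1-D vectors")
    if t.size == 0:
        raise ValueError("empty input")
    n = t.size
    _, gi = np.unique(g, return_inverse=True)
    h_cond = 0.0
    for v in range(gi.max() + 1):
        mask = gi == v
        nv = int(mask.sum())
        h_cond += (nv / n) * entropy(t[mask])
    return max(entropy(t) - h_cond, 0.0)


def balanced_accuracy(confusion: ContingencySummary) -> float:
    """(sensitivity + specificity) / 2 from confusion counts."""
    if confusion.tp + confusion.fn == 0:
        raise ValueError("no positive samples: sensitivity undefined")
    if confusion.tn + confusion.fp == 0:
        raise ValueError("no negative samples: specificity undefined")
    sens = confusion.tp / (confusion.tp + confusion.fn)
    spec = confusion.tn / (confusion.tn + confusion.fp)
    return (sens + spec) / 2.0


def cvc(per_fold_best: Sequence[Hashable], target: Hashable) -> int:
    """Number of CV folds in which ``target`` was the fold-best combination."""
    return sum(1 for best in per_fold_best if best == target)


def wcvc(per_fold_stats: Sequence[Mapping[Hashable, float]]) -> dict:
    """Weighted cross-validation consistency.

    ``per_fold_stats`` maps, for every fold, each candidate combination to
    its fold statistic. Each fold contributes ``stat / max-stat-in-fold``
    to every combination (0 for a fold whose statistics are all <= 0), so
    a combination strictly best in every fold scores ``n_folds`` and plain
    CVC is recovered when statistics are 0/1 indicators.
    """
    if not per_fold_stats:
        raise ValueError("no folds supplied")
    keys = set(per_fold_stats[0])
    for fold in per_fold_stats[1:]:
        if set(fold) != keys:
            raise ValueError("every fold must score the same combinations")
    scores = {k: 0.0 for k in keys}
    for fold in per_fold_stats:
        top = max(fold.values())
        if top <= 0:
            continue
        for k, stat in fold.items():
            scores[k] += stat / top
    return scores


def _entropy_from_counts(counts: np.ndarray, axis=None) -> np.ndarray:
    """Entropy (bits) of count arrays along ``axis`` (vectorized helper)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, counts / np.where(n > 0, n, 1.0), 0.0)
    h = -np.sum(xlogy(p, p), axis=axis) / np.log(2.0)
    return h


def _mi2x2(n11, n10, n01, n00):
    """Mutual information (bits) of 2x2 count tables, vectorized.

    Arguments are counts of (pred=1,truth=1), (pred=1,truth=0),
    (pred=0,truth=1), (pred=0,truth=0); any may be arrays.
    """
    n11, n10, n01, n00 = (np.asarray(a, dtype=float) for a in (n11, n10, n01, n00))
    cells = np.stack([n11, n10, n01, n00], axis=-1)
    rows = np.stack([n11 + n10, n01 + n00], axis=-1)
    cols = np.stack([n11 + n01, n10 + n00], axis=-1)
    mi = (
        _entropy_from_counts(rows, axis=-1)
        + _entropy_from_counts(cols, axis=-1)
        - _entropy_from_counts(cells, axis=-1)
    )
    return np.maximum(mi, 0.0)
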