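"""Benchmark metrics and multi-method concordance for binary RBP predictors.

Label 1 denotes RBP throughout.  The metric set mirrors what is commonly
reported for this task: F1, Matthews correlation coefficient, sensitivity
(recall on RBPs) and specificity (recall on Others), plus the area under
the precision-recall curve for score-producing methods, and Venn-style
concordance counts of correct positive predictions across methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts with label 1 = RBP."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Count TP/FP/TN/FN from equal-length binary vectors."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise ValueError("cannot build a confusion matrix from empty vectors")
    return ConfusionCounts(
        TP=int(((yt == 1) & (yp == 1)).sum()),
        FP=int(((yt == 0) & (yp == 1)).sum()),
        TN=int(((yt == 0) & (yp == 0)).sum()),
        FN=int(((yt == 1) & (yp == 0)).sum()),
    )


def metrics(cc: ConfusionCounts) -> dict[str, float]:
    """F1, MCC, sensitivity and specificity from confusion counts.

    A metric whose denominator is zero is reported as 0.0 with a warning,
    so degenerate predictors still produce a full row of numbers.
    """
    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0.0")
            return 0.0
        return num / den

    f1 = ratio(2 * cc.TP, 2 * cc.TP + cc.FP + cc.FN, "F1")
    sens = ratio(cc.TP, cc.TP + cc.FN, "sensitivity")
    spec = ratio(cc.TN, cc.TN + cc.FP, "specificity")
    denom = math.sqrt(
        float(cc.TP + cc.FP) * (cc.TP + cc.FN) * (cc.TN + cc.FP) * (cc.TN + cc.FN)
    )
    mcc = ratio(cc.TP * cc.TN - cc.FP * cc.FN, denom, "MCC")
    return {"F1": f1, "MCC": mcc, "sensitivity": sens, "specificity": spec}


def pr_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Thresholds sweep the distinct score values from high to low; the area
    is the sum of precision times the recall increment at each threshold
    (no interpolation between points).  Tied scores enter together.
    Raises if the truth contains a single class only.
    """
    yt = np.asarray(y_true, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if yt.shape != sc.shape:
        raise ValueError("y_true and scores must have the same length")
    n_pos = int((yt == 1).sum())
    if n_pos == 0 or n_pos == yt.size:
        raise ValueError("PR-AUC requires both classes in y_true")

    order = np.argsort(-sc, kind="stable")
    yt = yt[order]
    sc = sc[order]
    # indices where the threshold actually changes (last of each tie group)
    distinct = np.flatnonzero(np.r_[sc[1:] != sc[:-1], True])
    tp_cum = np.cumsum(yt == 1)[distinct].astype(float)
    fp_cum = np.cumsum(yt == 0)[distinct].astype(float)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


@dataclass
class ConcordanceTable:
    """Region counts of correct positive predictions across methods."""

    methods: list[str]
    regions: dict[frozenset, int]  # non-empty method subsets -> exclusive count
    missed_by_all: int
    n_positives: int

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def region(self, *methods: str) -> int:
        """Exclusive count of positives found by exactly these methods."""
        return self.regions.get(frozenset(methods), 0)

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "regions": {
                "&".join(sorted(k)): v for k, v in sorted(
                    self.regions.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "missed_by_all": self.missed_by_all,
            "n_positives": self.n_positives,
        }


def concordance(
    correct_positives: Mapping[str, set],
    all_positives: set,
) -> ConcordanceTable:
    """Exclusive Venn region counts over each method's correct positives.

    ``correct_positives`` maps a method name to the set of true RBPs it
    predicted correctly; every such set must be a subset of
    ``all_positives``.  All ``2^m - 1`` exclusive regions are counted,
    together with the positives missed by every method.
    """
    methods = list(correct_positives)
    for name, ids in correct_positives.items():
        extra = set(ids) - all_positives
        if extra:
            raise ValueError(
                f"method {name!r} claims ids outside the positive set: "
                f"{sorted(extra)[:5]}"
            )
    regions: dict[frozenset, int] = {}
    for r in range(1, len(methods) + 1):
        for subset in combinations(methods, r):
            inside = set(all_positives)
            for m in subset:
                inside &= set(correct_positives[m])
            for m in methods:
                if m not in subset:
                    inside -= set(correct_positives[m])
            regions[frozenset(subset)] = len(inside)
    union = set()
    for ids in correct_positives.values():
        union |= set(ids)
    return ConcordanceTable(
        methods=methods,
        regions=regions,
        missed_by_all=len(all_positives - union),
        n_positives=len(all_positives),
    )
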