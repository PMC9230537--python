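"""Independent oracles used by the test suite.

These deliberately avoid the implementation's dynamic-programming and
vectorised code paths: the Viterbi oracle enumerates every legal state
path recursively, and the PR-AUC oracle enumerates every threshold.
"""

from __future__ import annotations

import numpy as np

from rbpdetect.alphabet import AMINO_ACIDS
from rbpdetect.profile_hmm import (
    ProfileHMM,
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
)


def brute_force_viterbi(hmm: ProfileHMM, seq: str) -> float:
    """Best local log-odds by exhaustive enumeration of all state paths.

    Paths enter at any match state, traverse M/I/D states with the
    profile's transitions, and exit from any match state; flanking
    residues are background and contribute nothing.  Exponential in
    sequence and profile length — only usable on toy instances.
    """
    x = [AMINO_ACIDS.index(c) for c in seq]
    n, L = len(x), hmm.L
    with np.errstate(divide="ignore"):
        lm = np.log2(hmm.match_emissions) - np.log2(hmm.background)
        li = np.log2(hmm.insert_emissions) - np.log2(hmm.background)
        lt = np.log2(hmm.transitions)
    best = [-np.inf]

    def extend(state: str, k: int, i: int, score: float) -> None:
        if state == "M":
            best[0] = max(best[0], score)  # free exit from any match state
        nexts = []
        if state == "M":
            if k < L and i + 1 < n:
                nexts.append(("M", k + 1, i + 1, score + lt[k, T_MM] + lm[k, x[i + 1]]))
            if i + 1 < n:
                nexts.append(("I", k, i + 1, score + lt[k, T_MI] + li[k, x[i + 1]]))
            if k < L:
                nexts.append(("D", k + 1, i, score + lt[k, T_MD]))
        elif state == "I":
            if k < L and i + 1 < n:
                nexts.append(("M", k + 1, i + 1, score + lt[k, T_IM] + lm[k, x[i + 1]]))
            if i + 1 < n:
                nexts.append(("I", k, i + 1, score + lt[k, T_II] + li[k, x[i + 1]]))
        else:  # D
            if k < L and i + 1 < n:
                nexts.append(("M", k + 1, i + 1, score + lt[k, T_DM] + lm[k, x[i + 1]]))
            if k < L:
                nexts.append(("D", k + 1, i, score + lt[k, T_DD]))
        for s2, k2, i2, sc2 in nexts:
            if np.isfinite(sc2):
                extend(s2, k2, i2, sc2)

    for i in range(n):
        for a in range(1, L + 1):
            extend("M", a, i, lm[a - 1, x[i]])
    return best[0]


def random_toy_hmm(rng: np.random.Generator, L: int) -> ProfileHMM:
    """A random valid profile for oracle comparisons."""
    me = rng.dirichlet(np.ones(20) * 0.5, size=L)
    ie = rng.dirichlet(np.ones(20), size=L + 1)
    t = np.zeros((L + 1, 7))
    t[:, :3] = rng.dirichlet(np.ones(3), size=L + 1)
    t[:, 3:5] = rng.dirichlet(np.ones(2), size=L + 1)
    t[:, 5:7] = rng.dirichlet(np.ones(2), size=L + 1)
    t[0, 5], t[0, 6] = 1.0, 0.0
    t[L, 0] += t[L, 2]
    t[L, 2] = 0.0
    t[L, 5], t[L, 6] = 1.0, 0.0
    return ProfileHMM("toy", me, ie, t)


def pr_auc_by_threshold_enumeration(y_true, scores) -> float:
    """PR-AUC by explicitly evaluating every distinct score threshold."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    thresholds = sorted(set(s), reverse=True)
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        called = s >= t
        tp = int((y[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
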