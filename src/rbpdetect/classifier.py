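"""Gradient-boosted RBP/Other classification over protein embeddings.

Each protein is represented by a fixed-length numeric vector.  The primary
representation in production is a protein language-model embedding
(ProtBert-style, 1024 dimensions, supplied externally or through the
optional adapter); the built-in fallback is a deterministic hashed 3-mer
frequency vector, which needs no external weights.  An XGBoost binary
classifier is tuned and evaluated with nested stratified cross-validation:
the inner folds select ``max_depth`` and ``n_estimators`` by F1, the outer
folds measure F1 and PR-AUC without selection leakage.  Per-profile HMM bit
scores can be concatenated to the embedding as an extra feature block.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product as iterproduct
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .evaluate import confusion, metrics, pr_auc

#: Dimension of the hashed 3-mer fallback embedding.
KMER_DIM = 400
KMER_K = 3

#: Default hyperparameter grid; spans shallow-to-moderate trees and
#: moderate-to-long boosting schedules.
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [3, 5, 7],
    "n_estimators": [100, 300, 500],
}


@dataclass
class EmbeddingMatrix:
    """Fixed-length per-protein feature vectors with row identities."""

    ids: list[str]
    matrix: np.ndarray
    embedder_tag: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix rows must match the id list")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ClassifierBundle:
    """A fitted model together with its feature schema."""

    model: XGBClassifier
    hyperparameters: dict
    embed_dim: int
    hmm_names: list[str] = field(default_factory=list)
    embedder_tag: str = "kmer-fallback"
    decision_threshold: float = 0.5

    @property
    def input_dim(self) -> int:
        return self.embed_dim + len(self.hmm_names)


@dataclass
class CvReport:
    """Outer-fold metrics and selections of a nested cross-validation."""

    fold_f1: list[float]
    fold_pr_auc: list[float]
    fold_params: list[dict]
    fold_test_indices: list[np.ndarray]
    final_params: dict

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.fold_pr_auc))


def _kmer_index(kmer: str, d: int) -> int:
    digest = hashlib.md5(kmer.encode()).digest()
    return int.from_bytes(digest[:8], "big") % d


def embed(
    sequences: Sequence[str],
    ids: Sequence[str] | None = None,
    embedder: str = "kmer-fallback",
    k: int = KMER_K,
    d: int = KMER_DIM,
) -> EmbeddingMatrix:
    """Compute fixed-length embeddings for a batch of protein sequences.

    ``kmer-fallback`` hashes overlapping k-mers (stable MD5-based indices)
    into a ``d``-dimensional count vector normalised to frequencies — a
    deterministic, dependency-free representation.  ``language-model``
    requires externally computed embeddings (the pretrained weights are not
    bundled) and raises with advice to use the fallback or to pass a
    precomputed matrix downstream.
    """
    if embedder == "language-model":
        raise RuntimeError(
            "language-model embeddings require external pretrained weights; "
            "pass a precomputed EmbeddingMatrix, or use embedder='kmer-fallback'"
        )
    if embedder != "kmer-fallback":
        raise ValueError(f"unknown embedder {embedder!r}")
    if ids is None:
        ids = [f"seq{i}" for i in range(len(sequences))]
    X = np.zeros((len(sequences), d))
    cache: dict[str, int] = {}
    for row, seq in enumerate(sequences):
        seq = seq.upper()
        n_kmers = max(len(seq) - k + 1, 0)
        for i in range(n_kmers):
            kmer = seq[i : i + k]
            idx = cache.get(kmer)
            if idx is None:
                idx = cache[kmer] = _kmer_index(kmer, d)
            X[row, idx] += 1.0
        if n_kmers:
            X[row] /= n_kmers
    return EmbeddingMatrix(ids=list(ids), matrix=X, embedder_tag=embedder)


def fuse_features(
    embeddings: EmbeddingMatrix,
    hmm_scores: dict[str, np.ndarray],
    hmm_names: Sequence[str],
) -> EmbeddingMatrix:
    """Concatenate per-profile HMM bit scores to the embedding block.

    ``hmm_scores`` maps protein id to a vector of best bit scores in the
    fixed ``hmm_names`` order; proteins without an entry (no hit against
    any profile) get an all-zero block.
    """
    hmm_names = list(hmm_names)
    block = np.zeros((len(embeddings.ids), len(hmm_names)))
    known = set(embeddings.ids)
    for pid in hmm_scores:
        if pid not in known:
            raise ValueError(f"HMM scores given for unknown protein {pid!r}")
    for row, pid in enumerate(embeddings.ids):
        vec = hmm_scores.get(pid)
        if vec is not None:
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (len(hmm_names),):
                raise ValueError(
                    f"{pid}: score vector has shape {vec.shape}, "
                    f"expected ({len(hmm_names)},)"
                )
            block[row] = vec
    fused = np.hstack([embeddings.matrix, block])
    out = EmbeddingMatrix(
        ids=list(embeddings.ids),
        matrix=fused,
        embedder_tag=embeddings.embedder_tag + "+hmm",
    )
    return out


def _make_model(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        max_depth=params["max_depth"],
        n_estimators=params["n_estimators"],
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        verbosity=0,
    )


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    # direct F1 (no warnings): degenerate all-negative predictions score 0
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _select_params(
    X: np.ndarray,
    y: np.ndarray,
    grid_points: list[dict],
    k_inner: int,
    seed: int,
) -> dict:
    inner = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    best_score, best_params = -1.0, None
    for params in grid_points:
        scores = []
        for tr, va in inner.split(X, y):
            model = _make_model(params, seed)
            model.fit(X[tr], y[tr])
            pred = (model.predict_proba(X[va])[:, 1] >= 0.5).astype(int)
            scores.append(_f1(y[va], pred))
        score = float(np.mean(scores))
        if score > best_score:  # ties keep the earlier grid point
            best_score, best_params = score, params
    return best_params


def nested_cv(
    X: np.ndarray | EmbeddingMatrix,
    y: Sequence[int],
    grid: dict[str, list] | None = None,
    k_outer: int = 4,
    k_inner: int = 4,
    seed: int = 42,
) -> tuple[CvReport, ClassifierBundle]:
    """Nested stratified cross-validation of the XGBoost classifier.

    The inner loop selects the grid point with the best mean F1; the outer
    loop reports F1 and PR-AUC on each held-out fold.  The final model is
    refit on all data with hyperparameters selected by an inner-style CV
    over the full dataset.  Fully reproducible for a fixed seed.
    """
    emb = X if isinstance(X, EmbeddingMatrix) else None
    Xm = X.matrix if emb is not None else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    grid = grid or DEFAULT_GRID
    grid_points = [
        dict(zip(grid.keys(), values))
        for values in iterproduct(*grid.values())
    ]
    if not grid_points:
        raise ValueError("hyperparameter grid is empty")

    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    fold_f1, fold_ap, fold_params, fold_idx = [], [], [], []
    for tr, te in outer.split(Xm, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("a fold contains a single class; reduce k or rebalance")
        params = _select_params(Xm[tr], y[tr], grid_points, k_inner, seed)
        model = _make_model(params, seed)
        model.fit(Xm[tr], y[tr])
        scores = model.predict_proba(Xm[te])[:, 1]
        pred = (scores >= 0.5).astype(int)
        fold_f1.append(_f1(y[te], pred))
        fold_ap.append(pr_auc(y[te], scores))
        fold_params.append(params)
        fold_idx.append(te)

    final_params = _select_params(Xm, y, grid_points, k_inner, seed)
    final_model = _make_model(final_params, seed)
    final_model.fit(Xm, y)

    report = CvReport(
        fold_f1=fold_f1,
        fold_pr_auc=fold_ap,
        fold_params=fold_params,
        fold_test_indices=fold_idx,
        final_params=final_params,
    )
    bundle = ClassifierBundle(
        model=final_model,
        hyperparameters=final_params,
        embed_dim=Xm.shape[1] if emb is None else emb.d,
        embedder_tag=emb.embedder_tag if emb is not None else "matrix",
    )
    return report, bundle


def predict(
    bundle: ClassifierBundle,
    X: np.ndarray | EmbeddingMatrix,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Score proteins and threshold into RBP (1) / Other (0) labels.

    A score exactly at the threshold is called positive.  Raises on a
    feature-dimension mismatch, naming the expected and actual width.
    """
    Xm = X.matrix if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
    expected = bundle.input_dim
    if Xm.shape[1] != expected:
        raise ValueError(
            f"feature dimension mismatch: model expects {expected}, got {Xm.shape[1]}"
        )
    threshold = bundle.decision_threshold if threshold is None else threshold
    scores = bundle.model.predict_proba(Xm)[:, 1]
    labels = (scores >= threshold).astype(int)
    return labels, scores
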