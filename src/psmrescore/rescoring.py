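"""Iterative semi-supervised linear-SVM rescoring driven by target-decoy FDR.

The loop mirrors the Percolator recipe but is seeded with the universal XCorr
score instead of an engine-specific one: iteration 1 takes the targets that
pass the training FDR under XCorr as positives and random decoys as
negatives, fits a linear SVM, and re-scores every PSM; later iterations
re-select positives under the current SVM score.  Up to ``max_iterations``
rounds are run (ten by default), stopping early once the accepted-PSM count
stabilises; the result keeps whichever iteration's model accepted the most
targets at the training FDR.

Training uses a random subsample of at most 10,000 positives and 10,000
negatives — large experiments do not need every PSM to fit a stable linear
model.  Features are standardised to zero mean / unit variance with the
training-sample statistics each iteration (constant features get a unit
divisor); the final model scores all PSMs, including those sampled for
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .tdc import psms_at_fdr, qvalues_from_scores

__all__ = [
    "TrainingConfig",
    "IterationDiagnostics",
    "RescoringResult",
    "RescoringError",
    "select_training_sets",
    "fit_linear_model",
    "rescore_iteratively",
]


class RescoringError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    fdr_train: float = 0.01
    n_pos_sample: int = 10_000
    n_neg_sample: int = 10_000
    max_iterations: int = 10
    svm_cost: float = 1.0
    seed: int = 0
    convergence_tol: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.fdr_train < 1:
            raise ValueError("fdr_train must be in (0, 1)")
        if self.n_pos_sample < 1 or self.n_neg_sample < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationDiagnostics:
    iteration: int
    n_identified: int
    weights: np.ndarray
    bias: float


@dataclass
class RescoringResult:
    scores: np.ndarray
    qvalues: np.ndarray
    best_iteration: int
    history: list[IterationDiagnostics] = field(default_factory=list)

    @property
    def n_identified(self) -> int:
        return self.history[self.best_iteration - 1].n_identified


def select_training_sets(
    features,
    is_decoy: Sequence[bool],
    current_scores: Sequence[float],
    cfg: TrainingConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample positive/negative training indices under the current score.

    Positives: a uniform random sample of at most ``n_pos_sample`` targets
    with q <= ``fdr_train`` under ``current_scores``; negatives: at most
    ``n_neg_sample`` random decoys.
    """
    decoy = np.asarray(is_decoy, dtype=bool)
    scores = np.asarray(current_scores, dtype=float)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    q = qvalues_from_scores(scores, decoy)
    eligible = psms_at_fdr(q, decoy, cfg.fdr_train)
    if eligible.size == 0:
        raise RescoringError(
            f"no target PSMs pass q <= {cfg.fdr_train} under the current score; "
            "consider a looser fdr_train"
        )
    decoy_idx = np.flatnonzero(decoy)
    pos = rng.choice(eligible, size=min(cfg.n_pos_sample, eligible.size), replace=False)
    neg = rng.choice(decoy_idx, size=min(cfg.n_neg_sample, decoy_idx.size), replace=False)
    return np.sort(pos), np.sort(neg)


def fit_linear_model(
    X: np.ndarray, y: Sequence[int], cost: float = 1.0
) -> tuple[np.ndarray, float]:
    """Fit a linear SVM on standardised features; return (weights, bias).

    ``y`` holds +-1 labels.  The decision function is oriented so positives
    score higher on average.  The primal (dual=False) liblinear solver is used
    for determinism.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise RescoringError("training set contains a single class")
    clf = LinearSVC(C=cost, dual=False, max_iter=5000, tol=1e-5)
    clf.fit(X, y)
    w = clf.coef_.ravel().astype(float).copy()
    b = float(clf.intercept_[0])
    scores = X @ w + b
    if scores[y > 0].mean() < scores[y < 0].mean():
        w, b = -w, -b
    return w, b


def _standardize_params(Xtr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)  # constant features carry no signal
    return mu, sd


def rescore_iteratively(
    features,
    is_decoy: Sequence[bool],
    xcorr: Sequence[float],
    cfg: TrainingConfig = TrainingConfig(),
) -> RescoringResult:
    """Run the full iterative rescoring loop.

    ``features`` is the (n_psms, n_features) numeric matrix (expanded feature
    vectors, plus any pass-through tool scores); ``xcorr`` seeds the first
    round of training-set selection.  Returns final scores and q-values from
    the iteration whose model accepted the most targets at ``cfg.fdr_train``,
    plus per-iteration diagnostics.
    """
    X = np.asarray(features, dtype=float)
    decoy = np.asarray(is_decoy, dtype=bool)
    seed_scores = np.asarray(xcorr, dtype=float)
    if X.ndim != 2 or X.shape[0] != decoy.size or seed_scores.size != decoy.size:
        raise ValueError("features, is_decoy and xcorr must be aligned")
    if not decoy.any():
        raise RescoringError("no decoy PSMs: negative training set is empty")
    if decoy.all():
        raise RescoringError("no target PSMs to rescore")

    rng = np.random.default_rng(cfg.seed)
    current = seed_scores
    history: list[IterationDiagnostics] = []
    best: Optional[tuple[int, np.ndarray, int]] = None  # (count, scores, iteration)
    prev_count: Optional[int] = None

    for it in range(1, cfg.max_iterations + 1):
        pos, neg = select_training_sets(X, decoy, current, cfg, rng)
        Xtr = np.vstack([X[pos], X[neg]])
        ytr = np.concatenate([np.ones(pos.size, int), -np.ones(neg.size, int)])
        mu, sd = _standardize_params(Xtr)
        w, b = fit_linear_model((Xtr - mu) / sd, ytr, cfg.svm_cost)
        current = (X - mu) / sd @ w + b
        q = qvalues_from_scores(current, decoy)
        count = int(psms_at_fdr(q, decoy, cfg.fdr_train).size)
        history.append(IterationDiagnostics(it, count, w, b))
        if best is None or count > best[0]:
            best = (count, current.copy(), it)
        if prev_count is not None and abs(count - prev_count) < cfg.convergence_tol * max(
            prev_count, 1
        ):
            break
        prev_count = count

    assert best is not None
    final_scores = best[1]
    return RescoringResult(
        scores=final_scores,
        qvalues=qvalues_from_scores(final_scores, decoy),
        best_iteration=best[2],
        history=history,
    )
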