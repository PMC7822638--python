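"""Fisher-ratio feature ranking and inner-CV choice of the retained count S.

Features extracted by MPCA are ranked by the two-class Fisher discriminant
ratio F = (mu1 - mu0)^2 / (s1^2 + s0^2 + eps) with unbiased class
variances; the number S of top-ranked features to keep is chosen by
stratified 10-fold cross-validation on the training data only, scoring
each candidate S by mean held-out ROC AUC of the designated linear
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import CinempcaError

EPS = 1e-12  # guards degenerate (zero) class variances

DEFAULT_S_GRID = (1, 2, 5, 10, 20, 50, 100, 200)


@dataclass
class FeatureRanking:
    """Fisher ratios, the descending permutation over flat feature indices
    (ties broken by lower index), the selected count ``S`` and the inner-CV
    score trace per candidate S."""

    fisher_ratios: np.ndarray
    order: np.ndarray
    S: int | None = None
    inner_cv_scores: dict[int, float] | None = None

    def top(self, s: int) -> np.ndarray:
        """Flat indices of the ``s`` best-ranked features."""
        return self.order[:s]


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    m0, m1 = y == 0, y == 1
    if m0.sum() < 2 or m1.sum() < 2:
        raise CinempcaError("Fisher ratio requires >= 2 samples in each class")
    if m0.sum() + m1.sum() != y.size:
        raise CinempcaError("labels must be binary 0/1")
    return m0, m1


def fisher_ratio(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-class Fisher discriminant ratio of a single feature."""
    return float(fisher_ratios(np.asarray(values, float)[:, None], labels)[0])


def fisher_ratios(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Columnwise Fisher ratios of an (N, d) feature matrix."""
    x = np.asarray(features, dtype=float)
    m0, m1 = _check_classes(labels)
    mu0, mu1 = x[m0].mean(axis=0), x[m1].mean(axis=0)
    v0 = x[m0].var(axis=0, ddof=1)
    v1 = x[m1].var(axis=0, ddof=1)
    return (mu1 - mu0) ** 2 / (v0 + v1 + EPS)


def rank_features(features: np.ndarray, labels: np.ndarray) -> FeatureRanking:
    """Rank features by descending Fisher ratio (ties -> lower flat index)."""
    ratios = fisher_ratios(features, labels)
    order = np.lexsort((np.arange(ratios.size), -ratios))
    return FeatureRanking(fisher_ratios=ratios, order=order)


def default_s_grid(n_features: int) -> list[int]:
    grid = sorted({s for s in DEFAULT_S_GRID if s <= n_features} | {n_features})
    return grid


def select_S(
    features: np.ndarray,
    labels: np.ndarray,
    ranking: FeatureRanking | None = None,
    classifier_kind: str = "svm",
    S_grid: list[int] | None = None,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    metric: str = "auc",
) -> FeatureRanking:
    """Choose S by stratified inner cross-validation on the training data.

    For each candidate S the designated linear classifier is trained on the
    top-S features of each inner training fold and scored on the held-out
    inner fold (mean AUC by default; ``metric="accuracy"`` available).
    S is the argmax; ties go to the smallest S. Deterministic given the
    seed. The outer held-out data must never be passed here.
    """
    from .classify import train_classifier, decision_scores
    from .evaluate import roc_auc

    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if ranking is None:
        ranking = rank_features(x, y)
    d = x.shape[1]
    grid = sorted(set(S_grid)) if S_grid is not None else default_s_grid(d)
    if any(s < 1 or s > d for s in grid):
        raise CinempcaError(f"S_grid entries must lie in [1, {d}]")
    if len(y) < folds:
        raise CinempcaError(f"need at least {folds} samples for {folds}-fold inner CV")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    splits = list(skf.split(x, y))
    scores: dict[int, float] = {}
    for s in grid:
        cols = ranking.top(s)
        fold_scores = []
        for tr, te in splits:
            if len(np.unique(y[te])) < 2:
                raise CinempcaError("inner fold is missing a class; reduce fold count")
            model = train_classifier(x[np.ix_(tr, cols)], y[tr], kind=classifier_kind, C=C, seed=seed)
            sc = decision_scores(model, x[np.ix_(te, cols)])
            if metric == "auc":
                fold_scores.append(roc_auc(sc, y[te]))
            elif metric == "accuracy":
                fold_scores.append(float(((sc > 0).astype(int) == y[te]).mean()))
            else:
                raise CinempcaError(f"unknown inner-CV metric {metric!r}")
        scores[s] = float(np.mean(fold_scores))

    best = max(grid, key=lambda s: (scores[s], -s))
    return FeatureRanking(
        fisher_ratios=ranking.fisher_ratios,
        order=ranking.order,
        S=int(best),
        inner_cv_scores=scores,
    )
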