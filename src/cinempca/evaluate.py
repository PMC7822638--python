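"""Outer cross-validation of the full pipeline and ROC-based reporting.

The generalisation estimate follows a nested scheme: subjects are split
into 10 stratified outer folds; within each outer training split the MPCA
projection is fitted, features are Fisher-ranked, S is chosen by inner
10-fold CV, and the linear classifier is trained — the held-out fold is
only ever scored. The headline number is the mean of per-fold AUCs; pooled
held-out scores support the equal-sensitivity-specificity operating point
(its common value reported as accuracy, plus PPV and NPV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import CinempcaError, CineTensor, LandmarkSet
from .classify import LinearModel, decision_scores, train_classifier
from .mpca import MPCAModel, features_matrix, mpca_fit
from .preprocess import preprocess_dataset
from .selection import FeatureRanking, rank_features, select_S


def _check_both_classes(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise CinempcaError("both classes must be present")
    return y


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal ROC AUC with midrank tie handling (equals the normalised
    Mann-Whitney U statistic)."""
    y = _check_both_classes(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class OperatingPoint:
    """ROC operating point with (as nearly as the discrete ROC allows) equal
    sensitivity and specificity; ``accuracy`` is their common value
    ((sens + spec)/2 when they differ by the grid)."""

    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float


def equal_sens_spec(scores: np.ndarray, labels: np.ndarray) -> OperatingPoint:
    """Pick the threshold minimising |sensitivity - specificity|.

    Candidate thresholds are midpoints between adjacent distinct scores
    plus sentinels below/above all scores; positives are ``score >=
    threshold``. Ties on |sens - spec| go to the higher common value, then
    to the lower threshold. PPV/NPV come from the confusion counts at the
    chosen threshold.
    """
    y = _check_both_classes(labels)
    s = np.asarray(scores, dtype=float)
    distinct = np.unique(s)
    cands = [distinct[0] - 1.0]
    cands += list((distinct[:-1] + distinct[1:]) / 2.0)
    cands += [distinct[-1] + 1.0]

    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    best = None
    for thr in cands:
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        sens = tp / npos
        spec = tn / nneg
        key = (abs(sens - spec), -(sens + spec) / 2.0, thr)
        if best is None or key < best[0]:
            best = (key, thr, sens, spec, tp, tn)
    _, thr, sens, spec, tp, tn = best
    fp = nneg - tn
    fn = npos - tp
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return OperatingPoint(
        threshold=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float((sens + spec) / 2.0),
        ppv=float(ppv),
        npv=float(npv),
    )


@dataclass
class FoldModel:
    """Everything fitted on one outer training split."""

    mpca: MPCAModel
    ranking: FeatureRanking
    classifier: LinearModel


@dataclass
class CVResult:
    fold_test_indices: list[np.ndarray]
    fold_auc: np.ndarray
    mean_auc: float
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    fold_S: np.ndarray
    seed: int

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.pooled_scores, self.pooled_labels)

    def operating_point(self) -> OperatingPoint:
        return equal_sens_spec(self.pooled_scores, self.pooled_labels)


def fit_fold(
    train_tensors: np.ndarray,
    train_labels: np.ndarray,
    classifier_kind: str = "svm",
    variance_threshold: float = 0.97,
    S_grid: list[int] | None = None,
    inner_folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> FoldModel:
    """Fit MPCA, Fisher ranking, S (by inner CV) and the classifier on one
    training split. Nothing from any held-out data enters here."""
    y = _check_both_classes(train_labels)
    model = mpca_fit(train_tensors, variance_threshold=variance_threshold)
    feats = features_matrix(model, train_tensors)
    ranking = select_S(
        feats,
        y,
        ranking=rank_features(feats, y),
        classifier_kind=classifier_kind,
        S_grid=S_grid,
        folds=inner_folds,
        seed=seed,
        C=C,
    )
    cols = ranking.top(ranking.S)
    clf = train_classifier(
        feats[:, cols], y, kind=classifier_kind, C=C, seed=seed, selected=cols
    )
    return FoldModel(mpca=model, ranking=ranking, classifier=clf)


def score_fold(fold_model: FoldModel, tensors: np.ndarray) -> np.ndarray:
    """Apply a fitted fold model to new tensors; pure application, no fitting."""
    feats = features_matrix(fold_model.mpca, tensors)
    cols = fold_model.ranking.top(fold_model.ranking.S)
    return decision_scores(fold_model.classifier, feats[:, cols])


def outer_cv(
    tensors,
    labels: np.ndarray,
    classifier_kind: str = "svm",
    folds: int = 10,
    seed: int = 0,
    variance_threshold: float = 0.97,
    S_grid: list[int] | None = None,
    inner_folds: int = 10,
    C: float = 1.0,
) -> CVResult:
    """Stratified outer k-fold CV of the full pipeline.

    ``tensors`` is an (N, I, J, K) array (or list of arrays/CineTensors) of
    preprocessed sequences. Every sample is scored exactly once; per-fold
    AUCs, their mean, and the pooled held-out scores are returned.
    """
    x = tensors if isinstance(tensors, np.ndarray) else np.stack(
        [t.voxels if isinstance(t, CineTensor) else np.asarray(t, float) for t in tensors]
    )
    y = _check_both_classes(labels)
    n = x.shape[0]
    if n < folds:
        raise CinempcaError(f"need at least {folds} samples for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    fold_auc, fold_idx, fold_s = [], [], []
    pooled_scores = np.empty(n)
    for f, (tr, te) in enumerate(skf.split(x, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise CinempcaError("stratification failed: a fold is missing a class")
        inner_seed = (int(seed) * 1009 + f) % (2**31)
        fm = fit_fold(
            x[tr],
            y[tr],
            classifier_kind=classifier_kind,
            variance_threshold=variance_threshold,
            S_grid=S_grid,
            inner_folds=inner_folds,
            C=C,
            seed=inner_seed,
        )
        sc = score_fold(fm, x[te])
        pooled_scores[te] = sc
        fold_auc.append(roc_auc(sc, y[te]))
        fold_idx.append(te)
        fold_s.append(fm.ranking.S)
    return CVResult(
        fold_test_indices=fold_idx,
        fold_auc=np.asarray(fold_auc),
        mean_auc=float(np.mean(fold_auc)),
        pooled_scores=pooled_scores,
        pooled_labels=y.copy(),
        fold_S=np.asarray(fold_s),
        seed=int(seed),
    )


def scale_sweep(
    sequences: dict[str, CineTensor],
    landmarks3: dict[str, LandmarkSet],
    boundary5: LandmarkSet,
    labels: dict[str, int],
    reference_id: str,
    scales=(32, 64, 128),
    masks=("small", "large", "none"),
    classifiers=("svm", "lr"),
    folds: int = 10,
    seed: int = 0,
    dilation_factor: float = 1.5,
    **cv_kwargs,
) -> pd.DataFrame:
    """Mean outer-CV AUC for every (scale, mask, classifier) cell.

    Each cell is an independent :func:`outer_cv` run with the same seed on
    the correspondingly preprocessed dataset; the result is a tidy table
    (one row per cell) suitable for the scale-comparison summary.
    """
    rows = []
    for scale in scales:
        for mask in masks:
            processed, _ = preprocess_dataset(
                sequences,
                landmarks3,
                boundary5,
                reference_id,
                mask_variant=mask,
                scale=scale,
                dilation_factor=dilation_factor,
            )
            ids = list(processed)
            x = np.stack([processed[i].voxels for i in ids])
            y = np.array([labels[i] for i in ids])
            for clf in classifiers:
                res = outer_cv(x, y, classifier_kind=clf, folds=folds, seed=seed, **cv_kwargs)
                rows.append(
                    {
                        "scale": scale,
                        "mask": mask,
                        "classifier": clf,
                        "mean_auc": res.mean_auc,
                        "pooled_auc": res.pooled_auc,
                        "mean_S": float(res.fold_S.mean()),
                    }
                )
    return pd.DataFrame(rows)
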