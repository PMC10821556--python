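"""Multivariate views and the three-class random-forest evaluation.

A cohort labelled normal / benign / cancer is evaluated with a random forest
under stratified k-fold cross-validation.  Out-of-fold class probabilities
are pooled and scored with the one-vs-rest AUC family:

* NormalAUC / BenignAUC / CancerAUC — binary AUC of each class's predicted
  probability against membership of that class;
* MacroAUC — unweighted mean of the three per-label AUCs;
* MicroAUC — AUC on the flattened 3n-long label-indicator vector against the
  flattened probability matrix.

Feature selection ranks features by mean importance over repeated CV and
scans a grid of panel sizes k for the best mean MacroAUC.  PCA (on
standardized features) and a ridge-regularized Fisher LDA provide the
unsupervised / two-class views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .stats import roc_auc

__all__ = [
    "MulticlassAUCReport",
    "CVConfig",
    "pca_project",
    "lda_project",
    "rf_multiclass_cv",
    "multiclass_auc",
    "select_top_k",
]

log = logging.getLogger(__name__)

CLASS_ORDER = ("normal", "benign", "cancer")


@dataclass(frozen=True)
class MulticlassAUCReport:
    normal_auc: float
    benign_auc: float
    cancer_auc: float
    macro_auc: float
    micro_auc: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "NormalAUC": self.normal_auc,
            "BenignAUC": self.benign_auc,
            "CancerAUC": self.cancer_auc,
            "MacroAUC": self.macro_auc,
            "MicroAUC": self.micro_auc,
        }


@dataclass(frozen=True)
class CVConfig:
    """Random-forest cross-validation settings (library defaults: 500 trees,
    5 stratified folds; 20 repeats for feature selection)."""

    n_trees: int = 500
    folds: int = 5
    repeats: int = 1
    seed: int = 0
    feature_grid: Tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")


def pca_project(matrix: np.ndarray | pd.DataFrame, n_components: int | None = None):
    """Standardize features and decompose; returns (scores, loadings, explained variance ratio).

    Constant features are dropped with a warning before standardization.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs a 2-D matrix with >= 2 samples and >= 2 features")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.warning("pca_project: dropping %d constant feature(s)", int((~keep).sum()))
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant features")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    return scores, pca.components_, pca.explained_variance_ratio_


def lda_project(matrix: np.ndarray | pd.DataFrame, labels: Sequence, ridge: float = 1e-6):
    """Fisher discriminant direction for two classes with a ridge-stabilized
    pooled covariance; returns (weights, per-sample scores).

    The direction solves (S_w + ridge * tr(S_w)/p * I) w = mu_1 - mu_0, so it
    remains defined when the pooled scatter is singular (p > n).  Swapping
    the two labels negates weights and scores.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"LDA needs exactly two classes, got {classes.size}")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    p = X.shape[1]
    sw = np.zeros((p, p))
    for part in (X0, X1):
        d = part - part.mean(axis=0)
        sw += d.T @ d
    scale = np.trace(sw) / p if np.trace(sw) > 0 else 1.0
    w = np.linalg.solve(sw + ridge * scale * np.eye(p), X1.mean(axis=0) - X0.mean(axis=0))
    return w, X @ w


def multiclass_auc(probabilities: np.ndarray, labels: Sequence[str]) -> MulticlassAUCReport:
    """One-vs-rest, macro and micro AUC from a class-probability matrix.

    ``probabilities`` has one column per class in the order
    (normal, benign, cancer); rows must sum to 1.
    """
    P = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if P.shape != (y.size, 3):
        raise ValueError("probability matrix must be n x 3 in class order (normal, benign, cancer)")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    per_label = []
    for col, cls in enumerate(CLASS_ORDER):
        indicator = (y == cls).astype(int)
        if indicator.sum() == 0:
            raise ValueError(f"label {cls!r} absent; cannot compute its one-vs-rest AUC")
        per_label.append(roc_auc(P[:, col], indicator))
    indicator_matrix = np.stack([(y == cls).astype(int) for cls in CLASS_ORDER], axis=1)
    micro = roc_auc(P.ravel(), indicator_matrix.ravel())
    return MulticlassAUCReport(
        normal_auc=per_label[0],
        benign_auc=per_label[1],
        cancer_auc=per_label[2],
        macro_auc=float(np.mean(per_label)),
        micro_auc=micro,
    )


def _check_labels(y: np.ndarray, folds: int) -> None:
    for cls in CLASS_ORDER:
        n = int((y == cls).sum())
        if n < folds:
            raise ValueError(
                f"class {cls!r} has only {n} samples, fewer than {folds} folds; reduce the fold count"
            )


def rf_multiclass_cv(
    matrix: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    cfg: CVConfig = CVConfig(),
) -> Tuple[np.ndarray, MulticlassAUCReport, np.ndarray]:
    """Stratified k-fold random-forest CV of the three-class problem.

    Returns the out-of-fold probability matrix (n x 3, class order normal /
    benign / cancer), the pooled AUC report, and fold-averaged impurity
    feature importances.  Every sample is scored exactly once, by a model
    that never saw it.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    _check_labels(y, cfg.folds)
    oof = np.full((X.shape[0], 3), np.nan)
    importances = np.zeros(X.shape[1])
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed % (2**31))
    for fold, (train, test) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=cfg.n_trees, random_state=(cfg.seed + 1000 * fold) % (2**31), n_jobs=1
        )
        rf.fit(X[train], y[train])
        prob = rf.predict_proba(X[test])
        order = [list(rf.classes_).index(cls) for cls in CLASS_ORDER]
        oof[test] = prob[:, order]
        importances += rf.feature_importances_
    importances /= cfg.folds
    report = multiclass_auc(oof, y)
    return oof, report, importances


def select_top_k(
    matrix: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    cfg: CVConfig,
) -> Tuple[int, np.ndarray, Dict[int, float]]:
    """Panel-size selection by repeated cross-validation.

    Features are ranked by mean importance across ``cfg.repeats`` repeats of
    k-fold CV on all features; then for every k in ``cfg.feature_grid`` the
    top-k panel is re-evaluated by the same repeated CV and scored by mean
    MacroAUC.  Returns (optimal k, feature indices ranked by importance,
    {k: mean MacroAUC}).  Ties in the curve go to the smaller panel.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if cfg.repeats < 2:
        raise ValueError("feature selection needs repeats >= 2")
    grid = tuple(cfg.feature_grid) or (X.shape[1],)
    if max(grid) > X.shape[1]:
        log.warning("select_top_k: clipping grid to %d features", X.shape[1])
        grid = tuple(sorted({min(k, X.shape[1]) for k in grid}))

    total_importance = np.zeros(X.shape[1])
    for rep in range(cfg.repeats):
        rep_cfg = CVConfig(cfg.n_trees, cfg.folds, 1, cfg.seed + 7919 * rep)
        _, _, imp = rf_multiclass_cv(X, y, rep_cfg)
        total_importance += imp
    ranked = np.argsort(-total_importance, kind="stable")

    curve: Dict[int, float] = {}
    for k in grid:
        cols = ranked[:k]
        aucs: List[float] = []
        for rep in range(cfg.repeats):
            rep_cfg = CVConfig(cfg.n_trees, cfg.folds, 1, cfg.seed + 104729 * rep)
            _, report, _ = rf_multiclass_cv(X[:, cols], y, rep_cfg)
            aucs.append(report.macro_auc)
        curve[k] = float(np.mean(aucs))
    best_k = min(curve, key=lambda k: (-curve[k], k))
    return best_k, ranked, curve
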