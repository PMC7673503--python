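"""Pre-classification stages: Welch t-test gene screening, recursive feature
elimination, and SMOTE oversampling.

All three are fit on training data only. Inside a training fold the order is
normalize -> screen -> RFE -> SMOTE -> fit, so synthetic samples are
interpolated in selected-gene space and validation folds are never touched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

MAX_AUTO_GENES = 100  # auto mode never returns more than this many genes


@dataclass
class GeneScreenResult:
    """Per-gene Welch statistics at significance level ``alpha``."""

    gene_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    alpha: float

    @property
    def passed(self) -> np.ndarray:
        return self.p < self.alpha

    @property
    def passing_genes(self) -> list[str]:
        return [g for g, ok in zip(self.gene_ids, self.passed) if ok]


@dataclass
class FeatureSet:
    """Ordered gene selection produced by RFE."""

    gene_ids: list[str]
    mode: str  # "auto" | "fixed-10" | "fixed-25"
    cv_score: float | None = None  # 3-fold CV AUROC of the chosen set (auto mode)

    def __len__(self) -> int:
        return len(self.gene_ids)


def welch_screen(X, y, alpha: float = 0.1, gene_ids: list[str] | None = None) -> GeneScreenResult:
    """Welch two-sample t-test per gene between the +1 and -1 classes.

    Parameters
    ----------
    X:
        ExpressionMatrix (genes x samples) or ndarray of the same layout,
        restricted to labeled samples.
    y:
        +/-1 label vector aligned with samples.
    alpha:
        Two-sided significance level; a gene passes iff p < alpha.

    A gene with zero variance in both groups and equal means gets t = 0,
    p = 1 by convention (no evidence either way).
    """
    if isinstance(X, ExpressionMatrix):
        gene_ids = list(X.gene_ids)
        values = X.values
    else:
        values = np.asarray(X, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(values.shape[0])]
    y = np.asarray(y)
    pos = values[:, y == 1]
    neg = values[:, y == -1]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValueError(
            f"each class needs >= 2 samples for Welch's test "
            f"(got {pos.shape[1]} positive, {neg.shape[1]} negative)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes -> nan
        t, p = stats.ttest_ind(pos, neg, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return GeneScreenResult(gene_ids, t, p, alpha)


def remove_zero_variance(X: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop genes constant across all samples (t statistic undefined)."""
    keep = X.std(axis=1) > 0
    return X[keep], [g for g, k in zip(gene_ids, keep) if k]


def rfe_select(
    X,
    y,
    base_model,
    mode: str = "auto",
    inner_folds: int = 3,
    seed: int = 0,
    step: float = 0.1,
    gene_ids: list[str] | None = None,
) -> FeatureSet:
    """Recursive feature elimination over screened genes.

    ``mode`` is ``auto`` (best 3-fold CV AUROC among candidate sizes <= 100),
    ``fixed-10`` or ``fixed-25`` (exactly k genes). Each iteration drops the
    10% of remaining genes with the lowest model-native importance (absolute
    coefficient for linear models, impurity importance for tree ensembles;
    a linear-kernel surrogate ranks genes for RBF SVMs).

    If fewer genes are available than a fixed k requires, all are returned
    with a warning rather than an error.
    """
    from .classify import ModelSpec, make_rfe_estimator  # deferred: avoids cycle

    if isinstance(X, ExpressionMatrix):
        gene_ids = list(X.gene_ids)
        values = X.values
    else:
        values = np.asarray(X, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(values.shape[0])]
    y = np.asarray(y)
    if mode not in ("auto", "fixed-10", "fixed-25"):
        raise ValueError(f"unknown RFE mode {mode!r}")
    n_genes = len(gene_ids)
    if n_genes == 1:
        return FeatureSet(list(gene_ids), mode)

    algorithm = base_model.algorithm if isinstance(base_model, ModelSpec) else str(base_model)
    estimator = make_rfe_estimator(algorithm, seed)
    Xs = values.T  # samples x genes for sklearn

    if mode.startswith("fixed-"):
        k = int(mode.split("-")[1])
        if n_genes <= k:
            logger.warning(
                "RFE %s requested %d genes but only %d passed screening; keeping all",
                mode, k, n_genes,
            )
            return FeatureSet(list(gene_ids), mode)
        rfe = RFE(estimator, n_features_to_select=k, step=step)
        rfe.fit(Xs, (y == 1).astype(int))
        selected = [g for g, s in zip(gene_ids, rfe.support_) if s]
        return FeatureSet(selected, mode)

    return _rfe_auto(Xs, y, gene_ids, estimator, inner_folds, seed, step)


def _rfe_auto(Xs, y, gene_ids, estimator, inner_folds, seed, step) -> FeatureSet:
    """Shrink by `step` per iteration, scoring each candidate set <= 100 genes
    by stratified 3-fold CV AUROC; return the best-scoring set."""
    current = np.arange(len(gene_ids))
    best_idx, best_score = None, -np.inf
    while True:
        if len(current) <= MAX_AUTO_GENES:
            score = _cv_auroc(Xs[:, current], y, estimator, inner_folds, seed)
            if score > best_score:  # strict: prefer the larger (earlier) set on ties
                best_idx, best_score = current.copy(), score
        if len(current) == 1:
            break
        estimator.fit(Xs[:, current], (y == 1).astype(int))
        importance = _importances(estimator)
        n_drop = max(1, int(len(current) * step))
        keep_order = np.argsort(importance, kind="stable")[n_drop:]
        current = current[np.sort(keep_order)]
    selected = [gene_ids[i] for i in best_idx]
    return FeatureSet(selected, "auto", cv_score=float(best_score))


def _importances(estimator) -> np.ndarray:
    if hasattr(estimator, "coef_"):
        return np.abs(np.asarray(estimator.coef_)).ravel()
    return np.asarray(estimator.feature_importances_)


def _cv_auroc(Xs, y, estimator, folds, seed) -> float:
    from sklearn.base import clone

    folds = min(folds, int(min((y == 1).sum(), (y == -1).sum())))
    if folds < 2:
        return 0.5
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    y01 = (y == 1).astype(int)
    for tr, va in skf.split(Xs, y):
        est = clone(estimator)
        est.fit(Xs[tr], y01[tr])
        if hasattr(est, "predict_proba"):
            s = est.predict_proba(Xs[va])[:, -1]
        else:
            s = est.decision_function(Xs[va])
        if len(np.unique(y[va])) < 2:
            continue
        scores.append(roc_auc_score(y01[va], s))
    return float(np.mean(scores)) if scores else 0.5


def smote_oversample(
    X_train: np.ndarray,
    y_train: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``
    and ``x_nn`` one of the k nearest minority neighbors of a random minority
    sample ``x_i`` — a point on the segment between two real minority samples.
    Original rows are returned unchanged, synthetic rows appended.

    ``X_train`` is samples x features; ``y_train`` is +/-1.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    n_pos = int((y_train == 1).sum())
    n_neg = int((y_train == -1).sum())
    if n_pos == n_neg:
        return X_train, y_train
    minority_label = 1 if n_pos < n_neg else -1
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    if n_min < 2:
        raise ValueError("SMOTE needs >= 2 minority samples (no neighbor to interpolate)")
    k = min(k_neighbors, n_min - 1)
    minority = X_train[y_train == minority_label]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)  # +1: self is nearest
    neighbor_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x_i = minority[base]
    x_nn = minority[neighbor_idx[base, pick]]
    synthetic = x_i + u[:, None] * (x_nn - x_i)
    X_aug = np.vstack([X_train, synthetic])
    y_aug = np.concatenate([y_train, np.full(n_new, minority_label)])
    return X_aug, y_aug
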