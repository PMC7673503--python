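"""Classifier families, randomized hyperparameter tuning, and metrics.

A "model" is the full combination of algorithm, normalization, oversampling
choice, and gene-count mode — one :class:`ModelSpec`. Fitting a spec runs the
whole training pipeline (normalize -> Welch screen -> RFE -> SMOTE -> tune ->
fit) on the training samples only, and the resulting :class:`FittedModel`
carries everything needed to score new samples, including the frozen quantile
reference when quantile normalization was used.

Algorithms: L1-penalized logistic regression ("lasso"), random forest ("rf"),
gradient-boosted trees ("xgb", via xgboost), and an SVM with Platt-scaled
probabilities ("svm").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score as _sk_f1, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from .io import ExpressionMatrix
from .normalize import QuantileReference, rank_normalize, rpm_normalize
from .prep import FeatureSet, remove_zero_variance, rfe_select, smote_oversample, welch_screen

logger = logging.getLogger(__name__)

ALGORITHMS = ("lasso", "rf", "xgb", "svm")


def to01(y: np.ndarray) -> np.ndarray:
    """Map +/-1 labels to 0/1 (xgboost requires consecutive classes from 0)."""
    return (np.asarray(y) == 1).astype(int)

#: Default randomized-search spaces per algorithm. Each entry is
#: (kind, low, high) with kind in {"log-uniform", "int", "uniform"} or a
#: tuple of categorical choices. Override per-run via ``ModelSpec.search_space``.
DEFAULT_SEARCH_SPACES: dict[str, dict] = {
    "lasso": {"C": ("log-uniform", 1e-3, 1e3)},
    "rf": {
        "n_estimators": ("int", 100, 1000),
        "max_depth": ("int", 2, 10),
        "max_features": ("sqrt", "log2"),
    },
    "xgb": {
        "n_estimators": ("int", 100, 1000),
        "max_depth": ("int", 2, 10),
        "learning_rate": ("log-uniform", 0.01, 0.3),
    },
    "svm": {"C": ("log-uniform", 1e-3, 1e3), "kernel": ("rbf", "linear")},
}


@dataclass
class ModelSpec:
    """One candidate pipeline configuration."""

    algorithm: str = "lasso"
    normalization: str = "rank"
    oversampling: bool = False
    gene_mode: str = "auto"  # "auto" | "fixed-10" | "fixed-25"
    tuning_budget: int = 10
    tuning_folds: int = 3
    seed: int = 0
    alpha_screen: float = 0.1
    rfe_step: float = 0.1
    rfe_folds: int = 3
    smote_k: int = 5
    search_space: dict | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected {ALGORITHMS}")
        if self.tuning_budget < 1:
            raise ValueError("tuning_budget must be >= 1")

    def with_seed(self, seed: int) -> "ModelSpec":
        d = asdict(self)
        d["seed"] = int(seed)
        return ModelSpec(**d)

    def label(self) -> str:
        smote = "+SMOTE" if self.oversampling else ""
        return f"{self.algorithm}/{self.normalization}{smote}/{self.gene_mode}"


def sample_params(algorithm: str, rng: np.random.Generator, space: dict | None = None) -> dict:
    """Draw one random hyperparameter combination for ``algorithm``."""
    space = space if space is not None else DEFAULT_SEARCH_SPACES[algorithm]
    params = {}
    for name, dist in space.items():
        if isinstance(dist, tuple) and len(dist) == 3 and dist[0] == "log-uniform":
            lo, hi = np.log(dist[1]), np.log(dist[2])
            params[name] = float(np.exp(rng.uniform(lo, hi)))
        elif isinstance(dist, tuple) and len(dist) == 3 and dist[0] == "int":
            params[name] = int(rng.integers(dist[1], dist[2] + 1))
        elif isinstance(dist, tuple) and len(dist) == 3 and dist[0] == "uniform":
            params[name] = float(rng.uniform(dist[1], dist[2]))
        else:  # categorical
            params[name] = dist[int(rng.integers(len(dist)))]
    return params


def make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "lasso":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", random_state=seed, max_iter=2000, **params
        )
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            tree_method="hist",
            **params,
        )
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def make_rfe_estimator(algorithm: str, seed: int):
    """Mid-range default estimator used only to rank genes during RFE.

    RBF SVMs expose no per-gene weights, so a linear SVM surrogate ranks
    genes; trees use impurity importances, linear models |coefficients|.
    """
    if algorithm == "lasso":
        return LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                  random_state=seed, max_iter=2000)
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if algorithm == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=100, max_depth=3, random_state=seed, n_jobs=1,
                             eval_metric="logloss", verbosity=0, tree_method="hist")
    if algorithm == "svm":
        return LinearSVC(C=1.0, random_state=seed, max_iter=5000, dual="auto")
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class FittedModel:
    """A trained pipeline: spec + selected genes + classifier state."""

    spec: ModelSpec
    feature_set: FeatureSet
    estimator: object
    gene_universe: list[str]  # all training genes, needed to re-normalize new data
    quantile_reference: QuantileReference | None = None
    best_params: dict = field(default_factory=dict)
    tuning_scores: list = field(default_factory=list)
    # per-selected-gene standardization (training-fold statistics)
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def predict_proba(self, X_new: ExpressionMatrix) -> np.ndarray:
        """Probability of class +1 for each sample of ``X_new``.

        ``X_new`` must contain the model's full training gene universe:
        rank and RPM normalization are computed over all genes, so a reduced
        universe would distort the features.
        """
        missing = [g for g in self.gene_universe if g not in set(X_new.gene_ids)]
        if missing:
            shown = ", ".join(missing[:10])
            more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
            raise ValueError(f"X_new is missing required genes: {shown}{more}")
        X = X_new.subset_genes(self.gene_universe)
        X = self._normalize_new(X)
        Xs = X.subset_genes(self.feature_set.gene_ids).values.T
        if self.feature_mean is not None:
            Xs = (Xs - self.feature_mean) / self.feature_scale
        proba = self.estimator.predict_proba(Xs)
        pos_col = int(np.flatnonzero(np.asarray(self.estimator.classes_) == 1)[0])
        return proba[:, pos_col]

    def _normalize_new(self, X: ExpressionMatrix) -> ExpressionMatrix:
        method = self.spec.normalization
        if method == "rank":
            return rank_normalize(X)
        if method == "rpm":
            return rpm_normalize(X)
        return self.quantile_reference.transform(X)

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "spec": asdict(self.spec),
            "feature_genes": self.feature_set.gene_ids,
            "feature_mode": self.feature_set.mode,
            "gene_universe": self.gene_universe,
            "class_map": {"positive": 1, "negative": -1},
            "best_params": self.best_params,
            "feature_mean": None if self.feature_mean is None else list(map(float, self.feature_mean)),
            "feature_scale": None if self.feature_scale is None else list(map(float, self.feature_scale)),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        joblib.dump(self.estimator, directory / "estimator.joblib")
        if self.quantile_reference is not None:
            joblib.dump(self.quantile_reference, directory / "quantile_reference.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "FittedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        spec = ModelSpec(**manifest["spec"])
        estimator = joblib.load(directory / "estimator.joblib")
        qr_path = directory / "quantile_reference.joblib"
        qr = joblib.load(qr_path) if qr_path.exists() else None
        return cls(
            spec=spec,
            feature_set=FeatureSet(manifest["feature_genes"], manifest["feature_mode"]),
            estimator=estimator,
            gene_universe=manifest["gene_universe"],
            quantile_reference=qr,
            best_params=manifest["best_params"],
            feature_mean=None if manifest.get("feature_mean") is None
            else np.asarray(manifest["feature_mean"]),
            feature_scale=None if manifest.get("feature_scale") is None
            else np.asarray(manifest["feature_scale"]),
        )


def _normalize_train(X: ExpressionMatrix, method: str):
    """Normalize training data; return (normalized matrix, quantile reference or None)."""
    if method == "rank":
        return rank_normalize(X), None
    if method == "rpm":
        return rpm_normalize(X), None
    if method == "quantile":
        ref = QuantileReference.fit(X)
        return ref.transform(X), ref
    raise ValueError(f"unknown normalization {method!r}")


def tune_and_fit(X_train: ExpressionMatrix, y_train: np.ndarray, spec: ModelSpec) -> FittedModel:
    """Run the full training pipeline for one spec.

    Normalizes the training samples, screens genes with Welch's test at
    ``spec.alpha_screen``, selects genes by RFE, draws ``tuning_budget``
    random hyperparameter sets scored by mean stratified ``tuning_folds``-fold
    CV AUROC (SMOTE, when enabled, is applied inside each tuning-training
    split only), then refits the winner on the whole training set.
    """
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError("training data contains a single class; cannot fit a classifier")

    Xn, qref = _normalize_train(X_train, spec.normalization)
    values, genes = remove_zero_variance(Xn.values, list(Xn.gene_ids))
    screen = welch_screen(values, y_train, alpha=spec.alpha_screen, gene_ids=genes)
    passing = screen.passing_genes
    if not passing:
        # degenerate data; keep the 10 smallest-p genes so the pipeline can proceed
        order = np.argsort(screen.p, kind="stable")[:10]
        passing = [genes[i] for i in order]
        logger.warning("no gene passed screening at alpha=%s; keeping 10 smallest-p genes",
                       spec.alpha_screen)
    pos = {g: i for i, g in enumerate(genes)}
    screened = values[[pos[g] for g in passing]]
    # standardize per gene on training statistics: conditions the linear and
    # SVM fits and is what their regularization scales assume
    mu = screened.mean(axis=1, keepdims=True)
    sd = screened.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    screened = (screened - mu) / sd

    fs = rfe_select(
        screened, y_train, spec, mode=spec.gene_mode,
        inner_folds=spec.rfe_folds, seed=spec.seed, step=spec.rfe_step, gene_ids=passing,
    )
    ppos = {g: i for i, g in enumerate(passing)}
    sel_idx = [ppos[g] for g in fs.gene_ids]
    Xs = screened[sel_idx].T  # samples x genes

    rng = np.random.default_rng(spec.seed)
    draws = [sample_params(spec.algorithm, rng, spec.search_space)
             for _ in range(spec.tuning_budget)]
    scores = [_tuning_cv_auroc(Xs, y_train, spec, params) for params in draws]
    best = int(np.argmax(scores))  # ties -> first draw

    X_fit, y_fit = Xs, y_train
    if spec.oversampling:
        X_fit, y_fit = smote_oversample(Xs, y_train, k_neighbors=spec.smote_k, seed=spec.seed)
    estimator = make_estimator(spec.algorithm, draws[best], spec.seed)
    estimator.fit(X_fit, to01(y_fit))
    return FittedModel(
        spec=spec,
        feature_set=fs,
        estimator=estimator,
        gene_universe=list(Xn.gene_ids),
        quantile_reference=qref,
        best_params=draws[best],
        tuning_scores=[float(s) for s in scores],
        feature_mean=mu[sel_idx].ravel(),
        feature_scale=sd[sel_idx].ravel(),
    )


def _tuning_cv_auroc(Xs: np.ndarray, y: np.ndarray, spec: ModelSpec, params: dict) -> float:
    n_min = int(min((y == 1).sum(), (y == -1).sum()))
    folds = min(spec.tuning_folds, n_min)
    if folds < 2:
        return 0.5
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    scores = []
    for tr, va in skf.split(Xs, y):
        X_tr, y_tr = Xs[tr], y[tr]
        if spec.oversampling and int(min((y_tr == 1).sum(), (y_tr == -1).sum())) >= 2:
            X_tr, y_tr = smote_oversample(X_tr, y_tr, k_neighbors=spec.smote_k, seed=spec.seed)
        est = make_estimator(spec.algorithm, params, spec.seed)
        est.fit(X_tr, to01(y_tr))
        if len(np.unique(y[va])) < 2:
            continue
        pos_col = int(np.flatnonzero(np.asarray(est.classes_) == 1)[0])
        scores.append(roc_auc_score(y[va], est.predict_proba(Xs[va])[:, pos_col]))
    return float(np.mean(scores)) if scores else 0.5


def predict_proba(model: FittedModel, X_new: ExpressionMatrix) -> np.ndarray:
    """Probability of class +1 per sample (functional alias)."""
    return model.predict_proba(X_new)


def auroc(labels, probabilities) -> float:
    """Probability that a random +1 sample outranks a random -1 sample (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(probabilities, dtype=float)))


def f1_score(labels, predicted) -> float:
    """F1 of the +1 (minority) class; 0 when there are no positive predictions."""
    return float(_sk_f1(np.asarray(labels), np.asarray(predicted), pos_label=1, zero_division=0))
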