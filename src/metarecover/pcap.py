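"""PCAP: Proportion of Cases Accurately Predicted.

PCAP_x is the fraction of data whose label can be predicted at >= x%
precision. It is estimated by nested cross-validation: in each of
``outer_folds`` outer folds, an inner k-fold CV on the outer-training set
produces, for every integer percentile p in [50, 99] of the sorted predicted
probabilities, a per-inner-fold precision and recall when samples at or above
the p-th percentile are called +1. The smallest percentile whose precision
clears x% in the most inner folds becomes that outer fold's cutoff P_i, and
the mean recall at P_i across inner folds is that fold's PCAP contribution
R_i. The deployment cutoff is the mean of the P_i and the PCAP_x estimate is
the mean of the R_i; the outer-test folds report the precision actually
achieved at the calibrated cutoff.

Model selection compares candidate pipeline specs by the *median* of their
per-outer-fold PCAP values — more robust than the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import FittedModel, ModelSpec, auroc, f1_score, tune_and_fit
from .io import ExpressionMatrix

PERCENTILE_GRID = tuple(range(50, 100))  # integer percentiles 50..99 inclusive


@dataclass
class CutoffSelection:
    percentile: int
    mean_recall: float
    attainable: bool  # False when no percentile reached the target in any fold


@dataclass
class PcapEstimate:
    """Nested-CV PCAP estimate for one ModelSpec."""

    x: float  # target precision in percent (e.g. 90)
    fold_percentiles: list[int]  # P_i, one per outer fold
    fold_recalls: list[float]  # R_i (0 when the target was unattainable)
    fold_attainable: list[bool]
    test_precisions: list[float]  # achieved on outer-test folds at P_i (nan if no calls)
    test_recalls: list[float]
    pcap: float  # mean of fold_recalls
    deployment_cutoff: int  # mean of P_i, rounded to the nearest grid integer

    @property
    def median_fold_recall(self) -> float:
        return float(np.median(self.fold_recalls))


@dataclass
class CalibratedModel:
    """A fitted pipeline plus its precision-calibrated percentile cutoff."""

    model: FittedModel
    cutoff_percentile: int
    x: float
    # the cutoff percentile evaluated on the training cohort's probabilities:
    # an absolute fallback threshold for deployment under cohort shift
    frozen_threshold: float | None = None

    def __post_init__(self) -> None:
        if not 50 <= self.cutoff_percentile <= 99:
            raise ValueError("cutoff percentile must lie in [50, 99]")


def precision_recall_at_percentile(probs, labels, p) -> tuple[float, float]:
    """Precision and recall when the p-th percentile of ``probs`` is the cutoff.

    The threshold is the linearly-interpolated percentile of the probability
    vector itself; samples with prob >= threshold are called +1. Precision is
    nan (flagged undefined) if nothing is called; recall is 0 by convention
    when there are no true positives to recover.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    t = np.percentile(probs, p)
    called = probs >= t
    tp = int(np.sum(called & (labels == 1)))
    n_called = int(called.sum())
    n_pos = int((labels == 1).sum())
    precision = tp / n_called if n_called else float("nan")
    recall = tp / n_pos if n_pos else 0.0
    return precision, recall


def select_cutoff_percentile(
    per_fold_precisions: np.ndarray,
    per_fold_recalls: np.ndarray,
    x: float,
    grid=PERCENTILE_GRID,
) -> CutoffSelection:
    """Pick the calibration percentile from a k-folds x grid precision table.

    A cell votes 1 when its precision >= x/100. The smallest percentile with
    the most votes wins; the returned recall is the mean over folds of recall
    at that percentile (folds whose recall is nan — no positive validation
    samples — are skipped). If no percentile gets any vote the selection is
    flagged unattainable and pinned at percentile 99.
    """
    prec = np.asarray(per_fold_precisions, dtype=float)  # k x |grid|
    rec = np.asarray(per_fold_recalls, dtype=float)
    if prec.shape != rec.shape or prec.shape[1] != len(grid):
        raise ValueError("precision/recall tables must be k x |grid|")
    votes = np.nansum(prec >= x / 100.0, axis=0)  # nan precision never votes
    best = int(votes.max())
    if best == 0:
        j = len(grid) - 1
        recall = float(np.nanmean(rec[:, j])) if not np.all(np.isnan(rec[:, j])) else 0.0
        return CutoffSelection(percentile=int(grid[j]), mean_recall=recall, attainable=False)
    j = int(np.argmax(votes == best))  # smallest percentile among the argmax
    recall = float(np.nanmean(rec[:, j])) if not np.all(np.isnan(rec[:, j])) else 0.0
    return CutoffSelection(percentile=int(grid[j]), mean_recall=recall, attainable=True)


@dataclass
class FoldTables:
    """Raw nested-CV material for one outer fold (before choosing x)."""

    precisions: np.ndarray  # inner-folds x grid
    recalls: np.ndarray
    test_probs: np.ndarray  # outer-test probabilities from the outer-train fit
    test_labels: np.ndarray


def collect_fold_tables(
    X: ExpressionMatrix,
    y: np.ndarray,
    spec: ModelSpec,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> list[FoldTables]:
    """Run the nested CV once; PCAP for any target x is cheap post-processing.

    Every inner fold re-runs the whole training pipeline (screen, RFE, SMOTE,
    tuning) on its own training samples, so no information leaks from
    validation or test folds into calibration.
    """
    y = np.asarray(y)
    n_min = int(min((y == 1).sum(), (y == -1).sum()))
    if n_min < outer_folds:
        raise ValueError(
            f"minority class has {n_min} samples; stratified {outer_folds}-fold CV "
            f"needs at least {outer_folds}"
        )
    rng = np.random.default_rng(seed)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True,
                            random_state=int(rng.integers(2**31)))
    sample_ids = np.asarray(X.sample_ids)
    tables: list[FoldTables] = []
    for i, (tr, te) in enumerate(outer.split(sample_ids, y)):
        fold_seed = int(rng.integers(2**31))
        X_tr = X.subset_samples(list(sample_ids[tr]))
        y_tr = y[tr]
        inner_n = min(inner_folds, int(min((y_tr == 1).sum(), (y_tr == -1).sum())))
        inner = StratifiedKFold(n_splits=inner_n, shuffle=True, random_state=fold_seed)
        prec = np.full((inner_n, len(PERCENTILE_GRID)), np.nan)
        rec = np.full((inner_n, len(PERCENTILE_GRID)), np.nan)
        inner_ids = np.asarray(X_tr.sample_ids)
        for j, (itr, iva) in enumerate(inner.split(inner_ids, y_tr)):
            model = tune_and_fit(
                X_tr.subset_samples(list(inner_ids[itr])), y_tr[itr],
                spec.with_seed(fold_seed + j),
            )
            probs = model.predict_proba(X_tr.subset_samples(list(inner_ids[iva])))
            labels = y_tr[iva]
            has_pos = (labels == 1).any()
            for g, p in enumerate(PERCENTILE_GRID):
                pr, rc = precision_recall_at_percentile(probs, labels, p)
                prec[j, g] = pr
                rec[j, g] = rc if has_pos else np.nan  # skip fold in recall means
        outer_model = tune_and_fit(X_tr, y_tr, spec.with_seed(fold_seed))
        test_probs = outer_model.predict_proba(X.subset_samples(list(sample_ids[te])))
        tables.append(FoldTables(prec, rec, test_probs, y[te]))
    return tables


def pcap_from_tables(tables: list[FoldTables], x: float) -> PcapEstimate:
    """Turn raw nested-CV tables into a PCAP_x estimate (selection step only)."""
    fold_p, fold_r, fold_ok, test_p, test_r = [], [], [], [], []
    for ft in tables:
        sel = select_cutoff_percentile(ft.precisions, ft.recalls, x)
        fold_p.append(sel.percentile)
        fold_ok.append(sel.attainable)
        # an outer fold where the target precision is unattainable rescues
        # nothing: it contributes 0 recall to the PCAP mean
        fold_r.append(sel.mean_recall if sel.attainable else 0.0)
        pr, rc = precision_recall_at_percentile(ft.test_probs, ft.test_labels, sel.percentile)
        test_p.append(pr)
        test_r.append(rc)
    return PcapEstimate(
        x=x,
        fold_percentiles=fold_p,
        fold_recalls=fold_r,
        fold_attainable=fold_ok,
        test_precisions=test_p,
        test_recalls=test_r,
        pcap=float(np.mean(fold_r)),
        deployment_cutoff=int(np.clip(round(float(np.mean(fold_p))), 50, 99)),
    )


def estimate_pcap(
    X: ExpressionMatrix,
    y: np.ndarray,
    spec: ModelSpec,
    x: float = 90,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> PcapEstimate:
    """Nested-CV estimate of PCAP_x for one pipeline spec (see module docs)."""
    tables = collect_fold_tables(X, y, spec, outer_folds, inner_folds, seed)
    return pcap_from_tables(tables, x)


def select_model(
    candidates: list[ModelSpec],
    X: ExpressionMatrix,
    y: np.ndarray,
    criterion: str = "median-pcap",
    x: float = 90,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> tuple[ModelSpec, dict]:
    """Choose among candidate specs; ties go to the earlier candidate.

    ``median-pcap`` ranks by the median per-outer-fold PCAP_x recall (robust
    to one lucky fold); ``f1`` and ``auroc`` rank by the median outer-fold
    test metric under the same fold structure.
    """
    if not candidates:
        raise ValueError("need at least one candidate ModelSpec")
    if criterion not in ("median-pcap", "f1", "auroc"):
        raise ValueError(f"unknown criterion {criterion!r}")
    report: dict = {"criterion": criterion, "x": x, "candidates": []}
    scores = []
    estimates: list[PcapEstimate | None] = []
    for spec in candidates:
        if criterion == "median-pcap":
            est = estimate_pcap(X, y, spec, x, outer_folds, inner_folds, seed)
            score = est.median_fold_recall
            per_fold = est.fold_recalls
            estimates.append(est)
        else:
            per_fold = _outer_metric_folds(X, y, spec, criterion, outer_folds, seed)
            score = float(np.median(per_fold))
            estimates.append(None)
        scores.append(score)
        report["candidates"].append(
            {"spec": spec.label(), "median": score, "per_fold": list(map(float, per_fold))}
        )
    best = int(np.argmax(scores))
    report["winner"] = candidates[best].label()
    report["estimates"] = estimates
    return candidates[best], report


def _outer_metric_folds(X, y, spec, criterion, outer_folds, seed) -> list[float]:
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True,
                            random_state=int(rng.integers(2**31)))
    sample_ids = np.asarray(X.sample_ids)
    vals = []
    for tr, te in outer.split(sample_ids, y):
        fold_seed = int(rng.integers(2**31))
        model = tune_and_fit(X.subset_samples(list(sample_ids[tr])), y[tr],
                             spec.with_seed(fold_seed))
        probs = model.predict_proba(X.subset_samples(list(sample_ids[te])))
        if criterion == "auroc":
            vals.append(auroc(y[te], probs))
        else:
            preds = np.where(probs >= 0.5, 1, -1)
            vals.append(f1_score(y[te], preds))
    return vals


def calibrate(
    X: ExpressionMatrix,
    y: np.ndarray,
    spec: ModelSpec,
    x: float = 90,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> tuple[CalibratedModel, PcapEstimate]:
    """Estimate PCAP_x, then refit on all labeled data with the deployment cutoff."""
    est = estimate_pcap(X, y, spec, x, outer_folds, inner_folds, seed)
    model = tune_and_fit(X, y, spec.with_seed(seed))
    frozen = float(np.percentile(model.predict_proba(X), est.deployment_cutoff))
    return CalibratedModel(model, est.deployment_cutoff, x, frozen), est


def predict_confident(
    model: CalibratedModel,
    X_new: ExpressionMatrix,
    mode: str = "one-sided",
    c: float | None = None,
):
    """Predict only where the model is confident.

    One-sided mode thresholds at the deployment cutoff percentile of
    ``X_new``'s own probability distribution: samples at or above it are
    called +1, the rest abstain. ``frozen`` mode instead applies the absolute
    probability threshold recorded on the training cohort — safer when the
    new cohort's probability distribution may have shifted. Two-sided mode
    (for group comparisons) calls +1 when prob >= 1-c, -1 when prob < c
    (half-open [0, c)), and abstains on the middle band.

    Returns (probabilities, calls, abstained_ids); calls are +1/-1/0 with
    0 meaning abstain.
    """
    if X_new.n_samples == 0:
        raise ValueError("X_new has no samples")
    probs = model.model.predict_proba(X_new)
    calls = np.zeros(len(probs), dtype=int)
    if mode == "one-sided":
        t = np.percentile(probs, model.cutoff_percentile)
        calls[probs >= t] = 1
    elif mode == "frozen":
        if model.frozen_threshold is None:
            raise ValueError("model carries no frozen training threshold")
        calls[probs >= model.frozen_threshold] = 1
    elif mode == "two-sided":
        if c is None:
            raise ValueError("two-sided mode requires the confidence cutoff c")
        if not 0 < c <= 0.5:
            raise ValueError("c must lie in (0, 0.5]")
        calls[probs >= 1 - c] = 1
        calls[probs < c] = -1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    abstained = [s for s, call in zip(X_new.sample_ids, calls) if call == 0]
    return probs, calls, abstained


def two_sided_calls(probs: np.ndarray, c: float) -> np.ndarray:
    """+1 if prob >= 1-c, -1 if prob < c, 0 (abstain) otherwise."""
    probs = np.asarray(probs, dtype=float)
    if not 0 < c <= 0.5:
        raise ValueError("c must lie in (0, 0.5]")
    calls = np.zeros(len(probs), dtype=int)
    calls[probs >= 1 - c] = 1
    calls[probs < c] = -1
    return calls
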