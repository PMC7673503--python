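"""Differential gene expression analysis (DGEA) with predicted labels.

The point of recovering metadata is to reuse the expression data downstream.
This module measures how reliable that reuse is: per-gene Welch t-tests on
log2 values between two sample groups, overlap of significant-gene lists, a
five-arm comparison (true labels vs PCAP-calibrated predictions vs a newly
collected dataset vs permuted labels), and a sweep over the confidence cutoff
c that trades the accuracy of predicted groups against their size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .classify import ModelSpec
from .io import ExpressionMatrix
from .pcap import calibrate, two_sided_calls
from .prep import welch_screen

FIVEWAY_ARMS = ("True", "PCAP95", "PCAP90", "CollectNew", "Random")
DEFAULT_C_GRID = tuple(round(0.05 * i, 2) for i in range(1, 11))  # 0.05 .. 0.50


@dataclass
class DegList:
    """Genes declared differentially expressed between two groups."""

    variable: str
    group_sizes: tuple[int, int]
    gene_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    threshold: float
    significant: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.significant:
            self.significant = {
                g for g, pv in zip(self.gene_ids, self.p) if pv < self.threshold
            }


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_intersection: int
    percent: float  # relative to the reference list a


def deg_ttest(
    X: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    threshold: float = 0.05,
    log2_pseudocount: float = 1.0,
    adjust: str | None = None,
    variable: str = "",
) -> DegList:
    """Per-gene Welch t-test on log2(value + pseudocount) between two groups.

    ``adjust='bh'`` applies Benjamini-Hochberg and thresholds the adjusted
    p-values instead; the default (None) counts raw p < threshold, the
    convention used for overlap-count comparisons.
    """
    g1, g2 = list(group1), list(group2)
    overlap_ids = set(g1) & set(g2)
    if overlap_ids:
        raise ValueError(f"groups overlap: {sorted(overlap_ids)[:5]}")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(f"each group needs >= 2 samples (got {len(g1)}, {len(g2)})")
    sub = X.subset_samples(g1 + g2)
    logged = np.log2(sub.values + log2_pseudocount)
    y = np.concatenate([np.ones(len(g1), dtype=int), -np.ones(len(g2), dtype=int)])
    res = welch_screen(logged, y, alpha=threshold, gene_ids=list(sub.gene_ids))
    p = res.p
    if adjust == "bh":
        p = multipletests(res.p, method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    sig = {g for g, pv in zip(res.gene_ids, p) if pv < threshold}
    return DegList(variable, (len(g1), len(g2)), res.gene_ids, res.t, p, threshold, sig)


def overlap(a: DegList, b: DegList) -> OverlapResult:
    """Intersection of two significant-gene sets; percent relative to ``a``."""
    if set(a.gene_ids) != set(b.gene_ids):
        raise ValueError("DEG lists come from different gene universes")
    inter = a.significant & b.significant
    pct = 100.0 * len(inter) / len(a.significant) if a.significant else 0.0
    return OverlapResult(len(a.significant), len(b.significant), len(inter), pct)


def fiveway_overlap_experiment(
    X: ExpressionMatrix,
    y_true: np.ndarray,
    spec: ModelSpec | None = None,
    x_list: Sequence[float] = (95, 90),
    folds: int = 10,
    repeats: int = 50,
    threshold: float = 0.05,
    seed: int = 0,
    two_sided_c: float = 0.25,
    oracle_probs: np.ndarray | None = None,
    calibration_folds: tuple[int, int] = (10, 10),
) -> pd.DataFrame:
    """The five-arm DEG-overlap comparison.

    The labeled samples are split into ``folds`` stratified folds; each
    rotation treats 8 folds as training data (Dataset1), one fold as the
    dataset whose labels are predicted (Dataset2), and one fold as a newly
    collected labeled dataset (Dataset3). A reference list DEG1 comes from a
    one-fold-sized class-ratio-preserving subsample of Dataset1; the arms are
    DEG lists on Dataset2 with true labels (True), with confident predicted
    labels from a model calibrated at each target precision in ``x_list``
    (PCAP95/PCAP90), on Dataset3 (CollectNew), and on Dataset2 with permuted
    labels (Random). Overlap *counts* against DEG1 are averaged over the
    rotations; rows of the result are repeats, columns the five arms.

    ``oracle_probs`` (per-sample probabilities aligned with ``X``) bypasses
    model training — the synthetic-data test double for controlled-accuracy
    experiments. Prediction-based group membership uses the two-sided rule:
    +1 if prob >= 1 - c, -1 if prob < c, abstain otherwise.
    """
    from sklearn.model_selection import StratifiedKFold

    y_true = np.asarray(y_true)
    sample_ids = np.asarray(X.sample_ids)
    rng = np.random.default_rng(seed)
    arms = ["True"] + [f"PCAP{int(x)}" for x in x_list] + ["CollectNew", "Random"]
    rows = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        fold_idx = [te for _, te in skf.split(sample_ids, y_true)]
        per_rotation = {arm: [] for arm in arms}
        for i in range(folds):
            d2 = fold_idx[i]
            d3 = fold_idx[(i + 1) % folds]
            d1 = np.concatenate([fold_idx[j] for j in range(folds) if j not in (i, (i + 1) % folds)])
            deg1 = _deg_from_subsample(X, y_true, d1, len(d2), threshold, rng)
            deg2_t = _deg_on(X, y_true, d2, threshold)
            per_rotation["True"].append(_safe_count(deg1, deg2_t))
            for x in x_list:
                probs = _arm_probabilities(
                    X, y_true, d1, d2, spec, x, oracle_probs, calibration_folds, rng
                )
                calls = two_sided_calls(probs, two_sided_c)
                deg2_p = _deg_on_calls(X, sample_ids[d2], calls, threshold)
                per_rotation[f"PCAP{int(x)}"].append(_safe_count(deg1, deg2_p))
            deg3 = _deg_on(X, y_true, d3, threshold)
            per_rotation["CollectNew"].append(_safe_count(deg1, deg3))
            y_perm = y_true[d2].copy()
            rng.shuffle(y_perm)
            deg2_r = _deg_on(X, y_perm, np.arange(len(d2)), threshold,
                             subset=X.subset_samples(list(sample_ids[d2])))
            per_rotation["Random"].append(_safe_count(deg1, deg2_r))
        rows.append({arm: float(np.nanmean(per_rotation[arm])) for arm in arms})
    return pd.DataFrame(rows, columns=arms)


def _deg_from_subsample(X, y, idx, size, threshold, rng) -> DegList | None:
    """DEG list from a class-ratio-preserving subsample of `idx` of given size."""
    pos = idx[y[idx] == 1]
    neg = idx[y[idx] == -1]
    n_pos = max(2, int(round(size * len(pos) / len(idx))))
    n_neg = max(2, size - n_pos)
    take_pos = rng.choice(pos, size=min(n_pos, len(pos)), replace=False)
    take_neg = rng.choice(neg, size=min(n_neg, len(neg)), replace=False)
    sub = np.concatenate([take_pos, take_neg])
    return _deg_on(X, y, sub, threshold)


def _deg_on(X, y, idx, threshold, subset=None) -> DegList | None:
    ids = np.asarray(X.sample_ids) if subset is None else np.asarray(subset.sample_ids)
    mat = X if subset is None else subset
    g1 = list(ids[idx][y[idx] == 1])
    g2 = list(ids[idx][y[idx] == -1])
    if len(g1) < 2 or len(g2) < 2:
        return None
    return deg_ttest(mat, g1, g2, threshold)


def _deg_on_calls(X, ids, calls, threshold) -> DegList | None:
    g1 = list(np.asarray(ids)[calls == 1])
    g2 = list(np.asarray(ids)[calls == -1])
    if len(g1) < 2 or len(g2) < 2:
        return None
    return deg_ttest(X, g1, g2, threshold)


def _safe_count(a: DegList | None, b: DegList | None) -> float:
    if a is None or b is None:
        return np.nan
    return float(overlap(a, b).n_intersection)


def _arm_probabilities(X, y, d1, d2, spec, x, oracle_probs, calibration_folds, rng):
    sample_ids = np.asarray(X.sample_ids)
    if oracle_probs is not None:
        return np.asarray(oracle_probs, dtype=float)[d2]
    if spec is None:
        raise ValueError("either a ModelSpec or oracle_probs is required")
    cal, _ = calibrate(
        X.subset_samples(list(sample_ids[d1])), y[d1], spec, x=x,
        outer_folds=calibration_folds[0], inner_folds=calibration_folds[1],
        seed=int(rng.integers(2**31)),
    )
    return cal.model.predict_proba(X.subset_samples(list(sample_ids[d2])))


@dataclass
class CutoffSweepResult:
    c_grid: tuple
    percent_overlap: pd.DataFrame  # folds x c, nan where a group was too small
    best_c: float  # argmax of the median overlap across folds
    best_median: float


def cutoff_sweep(
    X: ExpressionMatrix,
    y_true: np.ndarray,
    fold_probs: Sequence[tuple[Sequence[str], np.ndarray]],
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    threshold: float = 0.05,
) -> CutoffSweepResult:
    """Sweep the two-sided confidence cutoff c and score DEG overlap vs truth.

    ``fold_probs`` holds, per CV fold, the held-out sample IDs and their
    predicted probabilities. For each c and fold, group 1 is the samples with
    prob in [0, c) and group 2 those in [1-c, 1]; the middle band is dropped.
    Overlap is the percentage of the all-sample true-label DEG list (DEG_t)
    recovered. Cells whose groups fall below 2 samples are undefined (nan)
    and excluded from the per-c medians.
    """
    y_true = np.asarray(y_true)
    ids = np.asarray(X.sample_ids)
    deg_t = _deg_on(X, y_true, np.arange(len(ids)), threshold)
    if deg_t is None:
        raise ValueError("cannot form the true-label DEG list (a class has < 2 samples)")
    table = np.full((len(fold_probs), len(c_grid)), np.nan)
    for i, (fold_ids, probs) in enumerate(fold_probs):
        probs = np.asarray(probs, dtype=float)
        for j, c in enumerate(c_grid):
            calls = two_sided_calls(probs, c)
            # [0, c) is group 1 (call -1), [1-c, 1] group 2 (call +1)
            deg_p = _deg_on_calls(X, list(fold_ids), calls, threshold)
            if deg_p is None:
                continue
            table[i, j] = overlap(deg_t, deg_p).percent
    df = pd.DataFrame(table, columns=[f"{c:g}" for c in c_grid])
    medians = np.nanmedian(table, axis=0)
    if np.all(np.isnan(medians)):
        best_j = len(c_grid) - 1
    else:
        best_j = int(np.nanargmax(medians))
    best_median = float(medians[best_j]) if not np.isnan(medians[best_j]) else float("nan")
    return CutoffSweepResult(tuple(c_grid), df, float(c_grid[best_j]), best_median)
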