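"""Synthetic expression data with known ground truth.

Emulates the structure the pipeline consumes in the wild: a genes x samples
matrix of nonnegative values, a binary clinical variable with class
imbalance, a subset of informative genes whose log2 mean shifts in the
minority class, per-sample library-scale factors (so per-sample
normalization is non-trivial), and missing-completely-at-random metadata.

Values are log-normal: 2^(baseline + shift + noise) times a sample scale
factor. That matches the continuous, roughly log-normal behavior of both
microarray intensities and per-million-scaled sequencing data; it does not
model sequencing count discreteness, batch effects, or gene-gene
correlation, so tests passing here say nothing about those.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import MISSING, ExpressionMatrix, MetadataTable

VARIABLE = "group"
POSITIVE, NEGATIVE = "pos", "neg"  # pos is the (minority) class of interest


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study conditions used in tests.

    ``effect_size`` is a log2-scale mean shift applied to informative genes
    in class +1; ``noise_sd`` is the log2-scale within-class standard
    deviation; ``library_scale_range`` bounds a per-sample multiplicative
    factor (uniform); ``missing_rate`` masks metadata values MCAR.
    """

    n_samples: int = 600
    n_genes: int = 2000
    n_informative: int = 50
    effect_size: float = 1.0
    minority_fraction: float = 0.25
    noise_sd: float = 1.0
    library_scale_range: tuple[float, float] = (0.5, 2.0)
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if not 0 < self.minority_fraction <= 0.5:
            raise ValueError("minority_fraction must lie in (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        lo, hi = self.library_scale_range
        if not 0 < lo <= hi:
            raise ValueError("library_scale_range must satisfy 0 < lo <= hi")


def generate(config: SyntheticConfig) -> tuple[ExpressionMatrix, MetadataTable, dict]:
    """Generate (expression, metadata, truth).

    The truth record carries the informative gene IDs and *all* labels,
    including the ones masked as missing in the metadata table — the
    ground truth that evaluation code scores against.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.n_samples
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    sample_ids = [f"sample{j:04d}" for j in range(m)]

    labels = np.where(rng.random(m) < config.minority_fraction, 1, -1)
    if (labels == 1).sum() < 2 or (labels == -1).sum() < 2:
        raise ValueError(
            "degenerate draw: a class has < 2 samples; increase n_samples or "
            "minority_fraction"
        )
    informative = rng.choice(n, size=config.n_informative, replace=False)
    informative_mask = np.zeros(n, dtype=bool)
    informative_mask[informative] = True

    baseline = rng.uniform(3.0, 10.0, size=n)  # log2-scale per-gene baseline
    shift = np.outer(informative_mask * config.effect_size, labels == 1)
    log2_values = baseline[:, None] + shift + rng.normal(0.0, config.noise_sd, size=(n, m))
    scale = rng.uniform(*config.library_scale_range, size=m)
    values = np.exp2(log2_values) * scale

    observed = [
        MISSING if rng.random() < config.missing_rate
        else (POSITIVE if lab == 1 else NEGATIVE)
        for lab in labels
    ]
    meta = MetadataTable(list(sample_ids), {VARIABLE: observed})
    truth = {
        "variable": VARIABLE,
        "informative_genes": [gene_ids[i] for i in sorted(informative)],
        "labels": {s: int(lab) for s, lab in zip(sample_ids, labels)},
        "config": asdict(config),
    }
    return ExpressionMatrix(gene_ids, sample_ids, values), meta, truth


def oracle_probabilities(truth: dict, error_rate: float = 0.0, seed: int = 0) -> np.ndarray:
    """Test-double probabilities with controlled accuracy.

    Each true +1 sample gets probability 1 - error_rate and each -1 sample
    error_rate; independently, each probability is flipped across 0.5 with
    probability ``error_rate``. At error_rate 0 the probabilities are exactly
    the {0, 1} truth. Sample order follows the truth record.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    labels = np.array(list(truth["labels"].values()))
    probs = np.where(labels == 1, 1.0 - error_rate, error_rate)
    flip = rng.random(len(probs)) < error_rate
    probs[flip] = 1.0 - probs[flip]
    return probs


def truth_labels(truth: dict, sample_ids=None) -> np.ndarray:
    """Ground-truth +/-1 labels, optionally reordered to ``sample_ids``."""
    if sample_ids is None:
        return np.array(list(truth["labels"].values()))
    return np.array([truth["labels"][s] for s in sample_ids])
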