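"""Expression-matrix / metadata I-O and binary label encoding.

Expression matrices are stored genes x samples (series-matrix convention)
regardless of the on-disk orientation. Metadata tables map each sample to
string-valued categorical variables with an explicit missing marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Strings parsed as a missing metadata value (case-insensitive), plus the
#: empty cell. GEO/TCGA dumps are inconsistent about this vocabulary.
DEFAULT_MISSING_VALUES = ("", "na", "nan", "unknown", "none", "missing", "not available")

MISSING = None  # canonical in-memory missing marker


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of nonnegative expression values.

    Units are platform-dependent (sequencing counts, microarray intensities,
    or already-normalized values); downstream code never assumes a unit.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value grid shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        neg = np.argwhere(self.values < 0)
        if neg.size:
            g, s = neg[0]
            raise ValueError(
                f"negative expression value {self.values[g, s]} at "
                f"gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[idx, :])


@dataclass
class MetadataTable:
    """Per-sample categorical annotations; ``None`` marks a missing value."""

    sample_ids: list[str]
    variables: dict[str, list]  # variable name -> per-sample value (str or None)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        for var, vals in self.variables.items():
            if len(vals) != len(self.sample_ids):
                raise ValueError(
                    f"variable {var!r} has {len(vals)} values for "
                    f"{len(self.sample_ids)} samples"
                )

    def values_for(self, variable: str) -> list:
        if variable not in self.variables:
            raise KeyError(
                f"variable {variable!r} not in metadata "
                f"(available: {sorted(self.variables)})"
            )
        return self.variables[variable]


@dataclass
class BinaryLabeling:
    """A categorical variable collapsed to a +/-1 vector.

    The minority class is coded +1 throughout the pipeline; samples whose
    value is missing or outside the allowed set are listed in ``excluded``.
    """

    variable: str
    positive_class: str
    negative_class: str
    sample_ids: list[str]
    labels: np.ndarray  # +/-1 ints, aligned with sample_ids
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be +/-1")
        if (self.labels == 1).sum() > (self.labels == -1).sum():
            raise ValueError("positive (+1) class must not outnumber negative class")

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == -1).sum())


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {kind} IDs: {', '.join(map(repr, dups))}")


def read_expression(path: str | Path, orientation: str = "genes-as-rows") -> ExpressionMatrix:
    """Read a TSV expression matrix (one header row, first column = IDs).

    Parameters
    ----------
    orientation:
        ``genes-as-rows`` (default, series-matrix layout) or ``samples-as-rows``.
    """
    if orientation not in ("genes-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "samples-as-rows":
        df = df.T
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"non-numeric or empty expression cell at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r} in {path}"
        )
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], values
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write genes-as-rows TSV (header = sample IDs, first column = gene ID)."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(
    path: str | Path, missing_values: Sequence[str] = DEFAULT_MISSING_VALUES
) -> MetadataTable:
    """Read a TSV metadata table (first column sample ID, one column per variable).

    Cells matching ``missing_values`` (case-insensitive) become the missing marker.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    lower = {m.lower() for m in missing_values}

    def clean(v: str):
        return MISSING if v.strip().lower() in lower else v.strip()

    variables = {str(c): [clean(v) for v in df[c]] for c in df.columns}
    return MetadataTable([str(s) for s in df.index], variables)


def write_metadata(meta: MetadataTable, path: str | Path, missing_string: str = "NA") -> None:
    df = pd.DataFrame(
        {
            var: [missing_string if v is MISSING else v for v in vals]
            for var, vals in meta.variables.items()
        },
        index=meta.sample_ids,
    )
    df.to_csv(path, sep="\t", index_label="sample_id")


def encode_binary_labels(
    meta: MetadataTable,
    variable: str,
    allowed_values: set[str] | None = None,
) -> BinaryLabeling:
    """Collapse a categorical variable to a +/-1 labeling.

    Samples with a missing value, or a value outside ``allowed_values``,
    are excluded. Without ``allowed_values``, the two most frequent values
    are kept (others excluded). The minority class is coded +1; an exact
    tie breaks toward the lexicographically smaller class label.
    """
    values = meta.values_for(variable)
    counts: dict[str, int] = {}
    for v in values:
        if v is MISSING:
            continue
        if allowed_values is not None and v not in allowed_values:
            continue
        counts[v] = counts.get(v, 0) + 1

    if len(counts) < 2:
        raise ValueError(
            f"variable {variable!r} has {len(counts)} usable class(es) after "
            f"filtering; need at least 2"
        )
    if allowed_values is not None and len(counts) != 2:
        raise ValueError(
            f"allowed_values for {variable!r} leave {len(counts)} classes; need exactly 2"
        )
    # two most frequent; ties broken lexicographically for determinism
    top2 = sorted(counts, key=lambda c: (-counts[c], c))[:2]
    a, b = top2
    if counts[a] < counts[b] or (counts[a] == counts[b] and a < b):
        positive, negative = a, b
    else:
        positive, negative = b, a

    retained: list[str] = []
    labels: list[int] = []
    excluded: list[str] = []
    for sid, v in zip(meta.sample_ids, values):
        if v == positive:
            retained.append(sid)
            labels.append(1)
        elif v == negative:
            retained.append(sid)
            labels.append(-1)
        else:
            excluded.append(sid)
    return BinaryLabeling(variable, positive, negative, retained, np.array(labels), excluded)
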