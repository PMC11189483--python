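"""Core containers shared across the NNICE pipeline.

Everything here is a thin, validated wrapper around numpy arrays with
explicit gene / column / cell-type identifiers, so that every module can
state its contract in terms of the same objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six pooled immune lineages the deconvolution model estimates.
POOLED_TYPES = ("B cell", "CD4 T cell", "CD8 T cell", "Myeloid", "NK cell", "Other")


@dataclass
class CountMatrix:
    """Integer expression matrix, genes x columns (cells or samples).

    Parameters
    ----------
    values
        Non-negative integer matrix of shape ``(n_genes, n_columns)``.
    gene_ids
        Ordered, unique gene identifiers (one per row).
    column_ids
        Ordered, unique cell barcodes or sample identifiers.
    labels
        Optional per-column cell-type label (same length as ``column_ids``).
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x columns)")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.column_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.column_ids)} column ids for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValueError("duplicate column ids")
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != len(self.column_ids):
                raise ValueError("labels length must match number of columns")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def select_columns(self, index: np.ndarray | list[int]) -> "CountMatrix":
        """Pure column selection; values are never altered."""
        index = np.asarray(index, dtype=int)
        return CountMatrix(
            values=self.values[:, index],
            gene_ids=list(self.gene_ids),
            column_ids=[self.column_ids[i] for i in index],
            labels=None if self.labels is None else [self.labels[i] for i in index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.column_ids == other.column_ids
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


@dataclass
class FractionMatrix:
    """Samples x cell-types matrix of fractions.

    Ground-truth tables have ``row_normalized=True`` and every row must sum
    to one within 1e-9. Estimate tables from per-type independent networks
    are not renormalized by default and carry ``row_normalized=False``,
    which relaxes the row-sum check (entries still lie in [0, 1]).
    """

    values: np.ndarray
    sample_ids: list[str]
    cell_type_names: list[str]
    row_normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x cell types)")
        n, k = self.values.shape
        if len(self.sample_ids) != n or len(self.cell_type_names) != k:
            raise ValueError("id lengths do not match matrix shape")
        if n and (np.any(self.values < 0) or np.any(self.values > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.row_normalized and n and (
            np.max(np.abs(self.values.sum(axis=1) - 1.0)) > 1e-9
        ):
            raise ValueError("every row must sum to 1 (within 1e-9)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_types(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.cell_type_names
        )


@dataclass
class QCMetrics:
    """Per-column quality metrics for a :class:`CountMatrix`.

    ``n_genes_by_counts`` counts genes with a positive count;
    ``pct_counts_mito`` is 100 x mitochondrial counts / total counts
    (defined as 0 for empty columns, which are flagged).
    """

    column_ids: list[str]
    n_genes_by_counts: np.ndarray
    total_counts: np.ndarray
    pct_counts_mito: np.ndarray
    zero_total_columns: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_genes_by_counts": self.n_genes_by_counts,
                "total_counts": self.total_counts,
                "pct_counts_mito": self.pct_counts_mito,
            },
            index=self.column_ids,
        )


@dataclass
class FeatureSet:
    """Ordered list of gene IDs defining the model's fixed input space."""

    genes: list[str]
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("feature set contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.genes) + "\n")

    @classmethod
    def read(cls, path) -> "FeatureSet":
        with open(path) as fh:
            genes = [line.strip() for line in fh if line.strip()]
        return cls(genes=genes)
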