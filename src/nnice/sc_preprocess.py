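"""Single-cell reference I/O, QC filtering, and cell-type pooling.

Cells are kept when they express between ``min_genes`` and ``max_genes``
features with positive counts (inclusive) and their mitochondrial read
percentage is strictly under ``max_mito_pct`` — boundary behaviour is
configurable. Fine-grained sorted populations are pooled into the six
lineages the estimator targets: B cell, CD4 T cell, CD8 T cell, Myeloid,
NK cell, Other.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .types import POOLED_TYPES, CountMatrix, QCMetrics

#: Pooling for the ten FACS-sorted PBMC populations.
TENX_POOLING_MAP: dict[str, str] = {
    "CD19+ B cells": "B cell",
    "CD14+ monocytes": "Myeloid",
    "CD34+ cells": "Other",
    "CD4+ helper T cells": "CD4 T cell",
    "CD4+/CD25+ regulatory T cells": "CD4 T cell",
    "CD4+/CD45RA+/CD25- naive T cells": "CD4 T cell",
    "CD4+/CD45RO+ memory T cells": "CD4 T cell",
    "CD56+ NK cells": "NK cell",
    "CD8+ cytotoxic T cells": "CD8 T cell",
    "CD8+/CD45RA+ naive cytotoxic T cells": "CD8 T cell",
}

#: Pooling for a 14-population flow-cytometry panel (whole-blood style).
#: Plasmablast and basophil assignments follow the standard lymphoid/
#: granulocyte lineage reading; override via a user TSV where needed.
FLOW_POOLING_MAP: dict[str, str] = {
    "B naive": "B cell",
    "B Ex": "B cell",
    "B NSM": "B cell",
    "B SM": "B cell",
    "Plasmablasts": "B cell",
    "CD4 T cells": "CD4 T cell",
    "CD8 T cells": "CD8 T cell",
    "Basophils": "Other",
    "mDCs": "Myeloid",
    "pDCs": "Myeloid",
    "NK cells": "NK cell",
    "Monocytes C": "Myeloid",
    "Monocytes I": "Myeloid",
    "Monocytes NC": "Myeloid",
}


def read_pooling_map(path) -> dict[str, str]:
    """Read a 2-column TSV (fine_type TAB pooled_type) into a mapping."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fine, pooled = line.split("\t")
        mapping[fine.strip()] = pooled.strip()
    bad = sorted(set(mapping.values()) - set(POOLED_TYPES))
    if bad:
        raise ValueError(f"pooled names not among {POOLED_TYPES}: {bad}")
    return mapping


def read_counts(
    path,
    format: str = "tenx_triplet",
    labels_path=None,
) -> CountMatrix:
    """Read a count matrix from a 10X-style triplet directory or dense TSV.

    ``tenx_triplet`` expects ``matrix.mtx`` + ``features.tsv`` (gene IDs in
    column 1) + ``barcodes.tsv`` under ``path``; ``dense_tsv`` expects a
    header row of column IDs and a first column of gene IDs. A labels file
    (barcode TAB cell_type) may be supplied either way; for a triplet
    directory containing ``labels.tsv`` it is picked up automatically.
    """
    path = Path(path)
    if format == "tenx_triplet":
        values = scipy.io.mmread(path / "matrix.mtx").toarray().astype(np.int64)
        gene_ids = [
            line.split("\t")[0]
            for line in (path / "features.tsv").read_text().splitlines()
            if line.strip()
        ]
        barcodes = [
            line.strip()
            for line in (path / "barcodes.tsv").read_text().splitlines()
            if line.strip()
        ]
        if values.shape[0] != len(gene_ids):
            raise ValueError(
                f"matrix has {values.shape[0]} rows but features.tsv lists "
                f"{len(gene_ids)} genes"
            )
        if values.shape[1] != len(barcodes):
            raise ValueError(
                f"matrix has {values.shape[1]} columns but barcodes.tsv lists "
                f"{len(barcodes)} barcodes"
            )
        if labels_path is None and (path / "labels.tsv").exists():
            labels_path = path / "labels.tsv"
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy().astype(np.int64)
        gene_ids = [str(g) for g in df.index]
        barcodes = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")

    labels = None
    if labels_path is not None:
        table: dict[str, str] = {}
        for line in Path(labels_path).read_text().splitlines():
            if line.strip():
                bc, lab = line.split("\t")
                table[bc.strip()] = lab.strip()
        missing = [b for b in barcodes if b not in table]
        if missing:
            raise ValueError(f"labels file missing {len(missing)} barcodes, "
                             f"e.g. {missing[:3]}")
        labels = [table[b] for b in barcodes]
    return CountMatrix(values=values, gene_ids=gene_ids, column_ids=barcodes,
                       labels=labels)


def compute_qc(
    matrix: CountMatrix,
    mito_prefix: str = "MT-",
    mito_genes: set[str] | None = None,
) -> QCMetrics:
    """Per-column QC: genes detected, total counts, % mitochondrial counts.

    Mitochondrial membership is decided by case-insensitive gene-ID prefix
    unless an explicit ``mito_genes`` set is given. Columns with zero total
    counts get ``pct_counts_mito = 0`` and are flagged.
    """
    if matrix.n_genes == 0 or matrix.n_columns == 0:
        raise ValueError("matrix must be non-empty")
    v = matrix.values
    if mito_genes is not None:
        is_mito = np.array([g in mito_genes for g in matrix.gene_ids])
    else:
        pref = mito_prefix.upper()
        is_mito = np.array([g.upper().startswith(pref) for g in matrix.gene_ids])
    total = v.sum(axis=0).astype(np.int64)
    n_pos = (v > 0).sum(axis=0).astype(np.int64)
    mito_total = v[is_mito].sum(axis=0) if is_mito.any() else np.zeros_like(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(total > 0, 100.0 * mito_total / np.maximum(total, 1), 0.0)
    zero_cols = [matrix.column_ids[i] for i in np.flatnonzero(total == 0)]
    return QCMetrics(
        column_ids=list(matrix.column_ids),
        n_genes_by_counts=n_pos,
        total_counts=total,
        pct_counts_mito=pct,
        zero_total_columns=zero_cols,
    )


def filter_cells(
    matrix: CountMatrix,
    qc: QCMetrics,
    min_genes: int = 200,
    max_genes: int = 3000,
    max_mito_pct: float = 5.0,
) -> CountMatrix:
    """Keep columns with min_genes <= detected <= max_genes (inclusive) and
    mito percentage strictly below ``max_mito_pct``. Order and labels are
    preserved; values are untouched (pure column selection)."""
    if qc.column_ids != matrix.column_ids:
        raise ValueError("qc was not computed from this matrix")
    keep = (
        (qc.n_genes_by_counts >= min_genes)
        & (qc.n_genes_by_counts <= max_genes)
        & (qc.pct_counts_mito < max_mito_pct)
    )
    if not keep.any():
        warnings.warn("all cells removed by QC filter", stacklevel=2)
    return matrix.select_columns(np.flatnonzero(keep))


def pool_cell_types(labels: list[str], mapping: dict[str, str]) -> list[str]:
    """Relabel fine cell types with their pooled lineage, element-wise."""
    unmapped = sorted({l for l in labels if l not in mapping})
    if unmapped:
        raise KeyError(f"labels missing from pooling map: {unmapped}")
    return [mapping[l] for l in labels]


def pool_matrix(matrix: CountMatrix, mapping: dict[str, str]) -> CountMatrix:
    """Return the same matrix with labels pooled through ``mapping``."""
    if matrix.labels is None:
        raise ValueError("matrix has no labels to pool")
    return CountMatrix(
        values=matrix.values,
        gene_ids=list(matrix.gene_ids),
        column_ids=list(matrix.column_ids),
        labels=pool_cell_types(matrix.labels, mapping),
    )
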