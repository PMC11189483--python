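"""Fixed input-space construction: immune-list / availability / variability.

The model needs the same ordered gene panel for every dataset it touches.
A gene enters the panel when it (1) appears in the immune-related gene
list, (2) is present in every dataset in play, and (3) ranks among the top
``n_features`` by a variance-stabilised highly-variable-gene score. The
eligibility criteria are intersected first and the top-n taken afterwards,
so the panel always has exactly ``n_features`` genes or fails loudly.

The variability score is the variance of depth-adjusted Pearson residuals
under a fixed-dispersion negative-binomial null: for gene g in cell c,
mu_gc = depth_c * p_g (depth_c the cell total, p_g the gene's pooled
proportion of all counts), residual = (x_gc - mu_gc) / sqrt(mu_gc +
mu_gc^2/theta) with theta = 100, clipped to +/- sqrt(n_cells). Genes whose
residual variance exceeds the ~1 expected under the null are the variable
ones; ties break lexicographically on gene ID so the order is total.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CountMatrix, FeatureSet

logger = logging.getLogger(__name__)


def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line gene list; de-duplicated, stripped."""
    genes = {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }
    if not genes:
        raise ValueError(f"gene list {path} is empty")
    return genes


def rank_variable_genes(
    matrix: CountMatrix,
    theta: float = 100.0,
    clip: float | None = None,
) -> pd.DataFrame:
    """Score and rank genes by clipped Pearson-residual variance.

    Returns a DataFrame indexed by gene ID with columns ``score`` and
    ``rank`` (0 = most variable). Zero-total genes score 0 and rank last.
    """
    if matrix.n_columns < 2:
        raise ValueError("need at least 2 columns to rank variability")
    x = matrix.values.astype(float)
    depth = x.sum(axis=0)  # per cell
    grand = depth.sum()
    gene_tot = x.sum(axis=1)
    p = gene_tot / grand if grand > 0 else np.zeros_like(gene_tot)
    mu = p[:, None] * depth[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (x - mu) / np.sqrt(mu + mu**2 / theta)
    resid[~np.isfinite(resid)] = 0.0
    if clip is None:
        clip = float(np.sqrt(matrix.n_columns))
    resid = np.clip(resid, -clip, clip)
    score = resid.var(axis=1)
    score[gene_tot == 0] = 0.0

    df = pd.DataFrame({"score": score}, index=pd.Index(matrix.gene_ids, name="gene"))
    df = df.sort_values(["score", "gene"], ascending=[False, True],
                        kind="mergesort")
    df["rank"] = np.arange(len(df))
    return df.loc[matrix.gene_ids]


def select_features(
    ranked: pd.DataFrame,
    immune_set: set[str],
    dataset_gene_sets: list[set[str]],
    n_features: int = 3000,
) -> FeatureSet:
    """Intersect eligibility criteria, then take the top-n by variability.

    eligible = immune_set ∩ (every dataset gene set) ∩ reference genes;
    the result lists the top ``n_features`` eligible genes in rank order.
    Raises if fewer than ``n_features`` genes are eligible, reporting the
    shortfall so the caller can lower ``n_features``.
    """
    reference_genes = set(ranked.index)
    eligible = immune_set & reference_genes
    for ds in dataset_gene_sets:
        eligible &= set(ds)
    sub = ranked.loc[ranked.index.isin(eligible)].sort_values("rank")
    if len(sub) < n_features:
        raise ValueError(
            f"only {len(sub)} genes satisfy all criteria; "
            f"{n_features - len(sub)} short of n_features={n_features}"
        )
    top = sub.iloc[:n_features]
    prov = pd.DataFrame(
        {
            "score": top["score"],
            "rank": top["rank"],
            "in_immune_list": True,
            "in_all_datasets": True,
        }
    )
    return FeatureSet(genes=list(top.index), provenance=prov)


def project_to_features(matrix: CountMatrix, fs: FeatureSet) -> CountMatrix:
    """Reorder rows to the feature-set order, zero-filling missing genes.

    Keeps the model input dimension fixed across datasets; missing genes
    are logged.
    """
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in fs.genes if g not in pos]
    if missing:
        logger.warning(
            "%d feature genes absent from matrix (zero-filled): %s%s",
            len(missing), missing[:5], "..." if len(missing) > 5 else "",
        )
    out = np.zeros((len(fs), matrix.n_columns), dtype=matrix.values.dtype)
    for i, g in enumerate(fs.genes):
        if g in pos:
            out[i] = matrix.values[pos[g]]
    return CountMatrix(
        values=out,
        gene_ids=list(fs.genes),
        column_ids=list(matrix.column_ids),
        labels=None if matrix.labels is None else list(matrix.labels),
    )
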