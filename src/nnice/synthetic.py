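"""Synthetic labeled single-cell references for testing the deconvolution stack.

The generator emulates the statistical structure the estimator relies on: a
panel of immune cell types with distinct expression signatures (exclusive
marker genes at a configurable fold-change), overdispersed counts
(negative-binomial via the gamma-Poisson mixture), independent technical
dropout, per-cell library-size variation, and a designated set of
mitochondrial genes (``MT-`` prefix) whose rates can be boosted to create
cells that fail the mitochondrial QC filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .types import CountMatrix

#: Fine-grained cell types of a FACS-sorted PBMC panel; these pool into the
#: six lineages in :data:`nnice.sc_preprocess.TENX_POOLING_MAP`.
DEFAULT_CELL_TYPES = (
    "CD19+ B cells",
    "CD14+ monocytes",
    "CD34+ cells",
    "CD4+ helper T cells",
    "CD4+/CD25+ regulatory T cells",
    "CD4+/CD45RA+/CD25- naive T cells",
    "CD4+/CD45RO+ memory T cells",
    "CD56+ NK cells",
    "CD8+ cytotoxic T cells",
    "CD8+/CD45RA+ naive cytotoxic T cells",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic single-cell generator.

    ``nb_dispersion`` is the negative-binomial shape theta
    (variance = mu + mu^2/theta); ``depth_range`` is the min/max of the
    per-cell uniform library-size multiplier; ``mito_boost`` multiplies the
    rates of mitochondrial genes so fixtures can produce high-mito cells.
    ``de_prob``/``de_sigma`` control the broad differential expression
    between types: each type multiplies a random ``de_prob`` fraction of
    gene rates by a lognormal(0, de_sigma) factor, so types differ modestly
    across many genes (as distinct sorted populations do) and not only at
    their exclusive markers.
    """

    n_genes: int = 1000
    n_cell_types: int = 10
    cells_per_type: int = 300
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.2
    marker_frac: float = 0.15
    marker_fold: float = 5.0
    de_prob: float = 0.3
    de_sigma: float = 0.6
    mito_frac: float = 0.02
    mito_boost: float = 1.0
    depth_range: tuple[float, float] = (0.5, 2.0)
    cell_type_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.cells_per_type < 1:
            raise ValueError("cells_per_type must be >= 1")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be 0 < lo <= hi")

    @property
    def cell_types(self) -> tuple[str, ...]:
        if self.cell_type_names is not None:
            if len(self.cell_type_names) != self.n_cell_types:
                raise ValueError("cell_type_names length must equal n_cell_types")
            return tuple(self.cell_type_names)
        if self.n_cell_types == len(DEFAULT_CELL_TYPES):
            return DEFAULT_CELL_TYPES
        return tuple(f"type{i:02d}" for i in range(self.n_cell_types))


@dataclass
class SignatureSet:
    """Per-(cell type, gene) expected expression rates plus marker metadata."""

    genes: list[str]
    cell_types: list[str]
    mean_rates: np.ndarray  # shape (n_cell_types, n_genes)
    marker_assignment: dict[str, str] = field(default_factory=dict)
    mito_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        if self.mean_rates.shape != (len(self.cell_types), len(self.genes)):
            raise ValueError("mean_rates shape must be (n_cell_types, n_genes)")
        if np.any(self.mean_rates < 0):
            raise ValueError("mean rates must be non-negative")
        if not self.mito_genes <= set(self.genes):
            raise ValueError("mito_genes must be a subset of genes")

    @property
    def marker_genes(self) -> list[str]:
        return [g for g in self.genes if g in self.marker_assignment]


def generate_signatures(config: SyntheticConfig) -> SignatureSet:
    """Draw per-type expression signatures.

    Baseline rates come from a long-tailed lognormal; marker genes are
    partitioned round-robin across cell types and boosted by
    ``marker_fold`` in their owning type only, so the fold-change invariant
    holds by construction. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    k, g = config.n_cell_types, config.n_genes
    n_markers = int(round(config.marker_frac * g))
    if 0 < n_markers < k:
        raise ValueError(
            f"marker_frac*n_genes = {n_markers} markers cannot cover "
            f"{k} cell types; increase n_genes or marker_frac"
        )

    n_mito = int(round(config.mito_frac * g))
    gene_ids = [f"GENE{i:05d}" for i in range(g)]
    # mito genes are ordinary genes flagged by ID prefix
    mito_idx = rng.choice(g, size=n_mito, replace=False) if n_mito else np.array([], int)
    for i in mito_idx:
        gene_ids[i] = f"MT-GENE{i:05d}"

    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    base[mito_idx] *= config.mito_boost
    rates = np.tile(base, (k, 1))
    if config.de_prob > 0:
        # broad per-type differential expression on a fraction of genes
        for t in range(k):
            de_mask = rng.random(g) < config.de_prob
            rates[t, de_mask] *= rng.lognormal(0.0, config.de_sigma,
                                               de_mask.sum())

    marker_assignment: dict[str, str] = {}
    if n_markers:
        # markers drawn from non-mito genes, assigned round-robin; the
        # owner's rate is pinned at marker_fold x the max over other types
        # so the fold-change invariant survives the DE perturbation
        candidates = np.setdiff1d(np.arange(g), mito_idx)
        marker_idx = rng.choice(candidates, size=min(n_markers, candidates.size),
                                replace=False)
        types = config.cell_types
        for j, gi in enumerate(marker_idx):
            owner = j % k
            others = np.delete(np.arange(k), owner)
            rates[owner, gi] = config.marker_fold * rates[others, gi].max()
            marker_assignment[gene_ids[gi]] = types[owner]

    return SignatureSet(
        genes=gene_ids,
        cell_types=list(config.cell_types),
        mean_rates=rates,
        marker_assignment=marker_assignment,
        mito_genes={gene_ids[i] for i in mito_idx},
    )


def simulate_cells(sig: SignatureSet, config: SyntheticConfig) -> CountMatrix:
    """Simulate a labeled reference of ``cells_per_type`` cells per type.

    Per cell: depth ~ U(depth_range); per gene: count ~ NB(mean = depth x
    rate, shape = nb_dispersion) via gamma-Poisson, then zeroed
    independently with probability ``dropout_rate``.
    """
    if list(sig.cell_types) != list(config.cell_types):
        raise ValueError("signature cell types do not match config")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    theta = config.nb_dispersion
    blocks, labels, barcodes = [], [], []
    for t, type_name in enumerate(sig.cell_types):
        n = config.cells_per_type
        depth = rng.uniform(*config.depth_range, size=n)
        mu = depth[None, :] * sig.mean_rates[t][:, None]  # genes x cells
        lam = rng.gamma(shape=theta, scale=np.where(mu > 0, mu / theta, 0.0))
        counts = rng.poisson(lam)
        if config.dropout_rate > 0:
            keep = rng.random(counts.shape) >= config.dropout_rate
            counts = counts * keep
        blocks.append(counts)
        labels.extend([type_name] * n)
        barcodes.extend(f"CELL-{t:02d}-{i:05d}" for i in range(n))
    return CountMatrix(
        values=np.concatenate(blocks, axis=1).astype(np.int64),
        gene_ids=list(sig.genes),
        column_ids=barcodes,
        labels=labels,
    )


def write_reference(matrix: CountMatrix, directory) -> dict[str, Path]:
    """Write a 10X-style triplet plus a barcode->label TSV.

    Emits ``matrix.mtx`` (sparse Matrix Market, genes x cells),
    ``features.tsv``, ``barcodes.tsv`` and ``labels.tsv``; round-trips
    losslessly through :func:`nnice.sc_preprocess.read_counts`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "features": directory / "features.tsv",
        "barcodes": directory / "barcodes.tsv",
        "labels": directory / "labels.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], scipy.sparse.csc_matrix(matrix.values))
    paths["features"].write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.gene_ids)
    )
    paths["barcodes"].write_text("".join(f"{b}\n" for b in matrix.column_ids))
    if matrix.labels is not None:
        paths["labels"].write_text(
            "".join(f"{b}\t{l}\n" for b, l in zip(matrix.column_ids, matrix.labels))
        )
    else:
        del paths["labels"]
    return paths


def make_immune_gene_list(
    sig: SignatureSet,
    path,
    nonmarker_frac: float = 0.5,
    seed: int = 0,
) -> Path:
    """Write a plain-text immune gene list (one symbol per line).

    Contains every marker gene plus a random ``nonmarker_frac`` of the
    remaining genes — a desk-scale stand-in for a curated
    immunologically-related gene list.
    """
    rng = np.random.default_rng(seed)
    markers = set(sig.marker_genes)
    nonmarkers = [g for g in sig.genes if g not in markers]
    n_extra = int(round(nonmarker_frac * len(nonmarkers)))
    extra = set(
        rng.choice(nonmarkers, size=n_extra, replace=False)) if n_extra else set()
    chosen = [g for g in sig.genes if g in markers or g in extra]
    path = Path(path)
    path.write_text("".join(f"{g}\n" for g in chosen))
    return path


def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["depth_range"] = list(d["depth_range"])
    return d
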