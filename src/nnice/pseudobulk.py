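"""Pseudo-bulk mixture simulation with known cell-type fractions.

A pseudo-bulk sample is built by (1) drawing a fraction vector for the K
pooled cell types from a Dirichlet distribution, (2) converting it to
integer cell counts summing to C (500 by default) by largest-remainder
rounding, (3) subsampling that many cells of each type from the reference
and summing their count vectors gene-wise. The stored ground truth is the
continuous Dirichlet draw, not the post-rounding realised proportion.

The reference cells used for mixing are split from those used for feature
selection (:func:`split_reference`) so marker selection cannot leak into
the simulated evaluation data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CountMatrix, FractionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PseudoBulkDataset:
    """Simulated mixtures: profiles (N x G counts), true fractions, and the
    reference column IDs summed into each sample."""

    profiles: np.ndarray
    gene_ids: list[str]
    fractions: FractionMatrix
    cells_used: list[list[str]]
    config: dict

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles)
        if self.profiles.shape[0] != self.fractions.n_samples:
            raise ValueError("profiles and fractions disagree on sample count")

    @property
    def n_samples(self) -> int:
        return self.profiles.shape[0]

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.profiles.T,
            index=self.gene_ids,
            columns=self.fractions.sample_ids,
        ).to_csv(directory / "profiles.tsv", sep="\t")
        self.fractions.to_frame().to_csv(directory / "fractions.csv")
        manifest = dict(self.config)
        manifest["cells_used_digest"] = [len(c) for c in self.cells_used]
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def split_reference(
    matrix: CountMatrix,
    frac_for_selection: float,
    seed: int,
) -> tuple[CountMatrix, CountMatrix]:
    """Stratified-by-type disjoint split into (selection, simulation) cells.

    Every cell lands in exactly one part; each type contributes
    ``round(frac_for_selection * n_type)`` cells (at least 1, at most
    n_type - 1) to the selection part. Deterministic given ``seed``.
    """
    if not 0 < frac_for_selection < 1:
        raise ValueError("frac_for_selection must be in (0, 1)")
    if matrix.labels is None:
        raise ValueError("reference must be labeled")
    rng = np.random.default_rng(seed)
    labels = np.asarray(matrix.labels)
    sel_idx: list[int] = []
    sim_idx: list[int] = []
    for t in sorted(set(matrix.labels)):
        idx = np.flatnonzero(labels == t)
        if idx.size < 2:
            raise ValueError(f"cell type {t!r} has {idx.size} cell(s); "
                             "cannot stratify the split")
        perm = rng.permutation(idx)
        n_sel = int(np.clip(round(frac_for_selection * idx.size), 1, idx.size - 1))
        sel_idx.extend(perm[:n_sel])
        sim_idx.extend(perm[n_sel:])
    return (
        matrix.select_columns(np.sort(sel_idx)),
        matrix.select_columns(np.sort(sim_idx)),
    )


def sample_fractions(
    n_samples: int,
    cell_type_names: list[str],
    dirichlet_alpha: float | np.ndarray = 1.0,
    seed: int = 0,
) -> FractionMatrix:
    """Draw i.i.d. Dirichlet fraction vectors, one row per sample."""
    k = len(cell_type_names)
    if k < 2:
        raise ValueError("need at least 2 cell types")
    alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (k,))
    if np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be positive")
    rng = np.random.default_rng(seed)
    values = rng.dirichlet(alpha, size=n_samples) if n_samples else np.zeros((0, k))
    return FractionMatrix(
        values=values,
        sample_ids=[f"S{i:05d}" for i in range(n_samples)],
        cell_type_names=list(cell_type_names),
    )


def allocate_cell_counts(fraction_row: np.ndarray, C: int = 500) -> np.ndarray:
    """Largest-remainder rounding of C x fractions to integers summing to C.

    Ties in the fractional remainders break by cell-type order.
    """
    f = np.asarray(fraction_row, dtype=float)
    if C < 1:
        raise ValueError("C must be >= 1")
    target = C * f
    base = np.floor(target).astype(int)
    shortfall = C - base.sum()
    # stable sort: descending remainder, ties by original position
    order = np.argsort(-(target - base), kind="stable")
    base[order[:shortfall]] += 1
    return base


def mix_profiles(
    simulation_cells: CountMatrix,
    counts_per_type: dict[str, int],
    seed: int,
) -> tuple[np.ndarray, list[str]]:
    """Subsample cells per type and sum their count vectors gene-wise.

    Sampling is uniform without replacement; when a type's pool is smaller
    than requested, sampling falls back to with-replacement (logged).
    Returns the 1 x G profile and the column IDs of the cells used.
    """
    if simulation_cells.labels is None:
        raise ValueError("simulation cells must be labeled")
    labels = np.asarray(simulation_cells.labels)
    available = set(simulation_cells.labels)
    rng = np.random.default_rng(seed)
    profile = np.zeros(simulation_cells.n_genes, dtype=np.int64)
    used: list[str] = []
    for t in sorted(counts_per_type):
        n = counts_per_type[t]
        if n == 0:
            continue
        if t not in available:
            raise KeyError(f"cell type {t!r} requested but absent from reference")
        pool = np.flatnonzero(labels == t)
        replace = pool.size < n
        if replace:
            logger.info("type %s: pool %d < requested %d, sampling with "
                        "replacement", t, pool.size, n)
        chosen = rng.choice(pool, size=n, replace=replace)
        profile += simulation_cells.values[:, chosen].sum(axis=1)
        used.extend(simulation_cells.column_ids[i] for i in chosen)
    return profile, used


def simulate_dataset(
    reference: CountMatrix,
    n_samples: int = 10_000,
    C: int = 500,
    dirichlet_alpha: float | np.ndarray = 1.0,
    seed: int = 0,
    cell_type_names: list[str] | None = None,
) -> PseudoBulkDataset:
    """Simulate a full pseudo-bulk dataset from a labeled, pooled reference.

    The stored fractions are the Dirichlet draws; realised cell-count
    proportions differ from them by at most K/(2C) per type under
    largest-remainder rounding.
    """
    if reference.labels is None:
        raise ValueError("reference must be labeled")
    if cell_type_names is None:
        cell_type_names = sorted(set(reference.labels))
    fractions = sample_fractions(n_samples, cell_type_names, dirichlet_alpha, seed)
    ss = np.random.SeedSequence([seed, n_samples, C]).spawn(max(n_samples, 1))
    profiles = np.zeros((n_samples, reference.n_genes), dtype=np.int64)
    cells_used: list[list[str]] = []
    for i in range(n_samples):
        counts = allocate_cell_counts(fractions.values[i], C)
        per_type = {t: int(c) for t, c in zip(cell_type_names, counts)}
        profiles[i], used = mix_profiles(
            reference, per_type, seed=ss[i].generate_state(1)[0] % (2**31)
        )
        cells_used.append(used)
    return PseudoBulkDataset(
        profiles=profiles,
        gene_ids=list(reference.gene_ids),
        fractions=fractions,
        cells_used=cells_used,
        config={
            "n_samples": n_samples,
            "C": C,
            "dirichlet_alpha": np.broadcast_to(
                np.asarray(dirichlet_alpha, float), (len(cell_type_names),)
            ).tolist(),
            "seed": seed,
            "cell_types": list(cell_type_names),
        },
    )
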