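"""End-to-end pipeline on a synthetic reference: the package's own benchmark.

Runs the whole method at desk scale: generate a labeled synthetic
single-cell reference, QC-filter it, pool the ten fine types into the six
lineages, split cells between feature selection and simulation, build the
immune-list/availability/variability feature panel, simulate training and
held-out pseudo-bulk mixtures, train the quantile networks, and score the
held-out set. Returns every intermediate artifact so tests can probe any
stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import feature_select as fsel
from . import pseudobulk as pb
from . import sc_preprocess as scp
from . import synthetic as syn
from .model import ModelConfig, NNICEModel, aggregate_quantiles, build_model, predict, train
from .types import CountMatrix, FractionMatrix


@dataclass
class BenchmarkResult:
    reference: CountMatrix
    feature_genes: list[str]
    model: NNICEModel
    test_fractions: FractionMatrix
    test_estimates: np.ndarray  # (n, K, |quantiles|)
    overall_r: float
    report: pd.DataFrame


def run_headline_benchmark(
    seed: int = 0,
    n_genes: int = 1000,
    cells_per_type: int = 300,
    marker_fold: float = 5.0,
    dropout_rate: float = 0.2,
    n_features: int = 300,
    n_train: int = 2000,
    n_test: int = 500,
    C: int = 500,
    dirichlet_alpha: float = 1.0,
    hidden_units: int = 64,
    epochs: int = 30,
    loss_mode: str = "signed",
) -> BenchmarkResult:
    """Simulated-data deconvolution benchmark; see module docstring.

    The defaults are the package's standard desk-scale conditions: 10 cell
    types pooled to 6 lineages, 1,000 genes, 300 cells/type, marker
    fold-change 5, dropout 0.2; 2,000 training and 500 held-out mixtures of
    C=500 cells with Dirichlet(1) fractions; 300 selected features and
    64 hidden units.
    """
    seed = int(seed) % (2**31)
    sc_cfg = syn.SyntheticConfig(
        n_genes=n_genes,
        cells_per_type=cells_per_type,
        marker_fold=marker_fold,
        dropout_rate=dropout_rate,
        seed=seed,
    )
    sig = syn.generate_signatures(sc_cfg)
    cells = syn.simulate_cells(sig, sc_cfg)
    qc = scp.compute_qc(cells, mito_genes=sig.mito_genes)
    cells = scp.filter_cells(cells, qc, min_genes=min(200, n_genes // 5),
                             max_genes=3000)
    pooled = scp.pool_matrix(cells, scp.TENX_POOLING_MAP)

    selection_cells, simulation_cells = pb.split_reference(
        pooled, frac_for_selection=1 / 3, seed=seed + 1
    )
    with TemporaryDirectory() as td:
        gene_list = syn.make_immune_gene_list(
            sig, Path(td) / "immune.txt", nonmarker_frac=0.5, seed=seed
        )
        immune = fsel.read_gene_list(gene_list)
    ranked = fsel.rank_variable_genes(selection_cells)
    feature_set = fsel.select_features(ranked, immune, [], n_features=n_features)

    cell_types = sorted(set(pooled.labels))
    train_ds = pb.simulate_dataset(
        simulation_cells, n_samples=n_train, C=C,
        dirichlet_alpha=dirichlet_alpha, seed=seed + 2,
        cell_type_names=cell_types,
    )
    test_ds = pb.simulate_dataset(
        simulation_cells, n_samples=n_test, C=C,
        dirichlet_alpha=dirichlet_alpha, seed=seed + 3,
        cell_type_names=cell_types,
    )

    def to_features(ds: pb.PseudoBulkDataset) -> np.ndarray:
        cm = CountMatrix(
            values=ds.profiles.T,
            gene_ids=ds.gene_ids,
            column_ids=ds.fractions.sample_ids,
        )
        return fsel.project_to_features(cm, feature_set).values.T

    cfg = ModelConfig(
        n_features=n_features,
        hidden_units=hidden_units,
        epochs=epochs,
        loss_mode=loss_mode,
        seed=seed,
    )
    model = build_model(cfg, cell_types, feature_set)
    train(model, to_features(train_ds), train_ds.fractions)
    est = predict(model, to_features(test_ds))
    overall = ev.overall_pearson_r(test_ds.fractions, est)
    report = ev.evaluate_predictions(
        test_ds.fractions, est, cfg.quantiles, cfg.alpha_mix
    )
    return BenchmarkResult(
        reference=pooled,
        feature_genes=list(feature_set.genes),
        model=model,
        test_fractions=test_ds.fractions,
        test_estimates=est,
        overall_r=float(overall),
        report=report,
    )
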