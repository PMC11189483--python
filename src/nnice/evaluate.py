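"""Evaluation: metrics at three granularities, k-fold CV, truth normalization.

Reports carry Pearson R, RMSE and the composite loss alpha*(1-R) +
(1-alpha)*RMSE per (cell type x quantile), per cell type on the
quantile-averaged estimate, and overall. "Overall" means the metric applied
to the concatenation of all (sample, type) pairs — not the mean of per-type
values, which can differ substantially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .losses import pearson_r, rmse
from .model import ModelConfig, NNICEModel, aggregate_quantiles, build_model, predict, train
from .types import FeatureSet, FractionMatrix


def normalize_true_fractions(raw: pd.DataFrame) -> FractionMatrix:
    """Zero-fill missing entries and renormalize each row to sum to one.

    ``raw`` is samples x cell-types with NaN for missing measurements.
    Negative entries and all-zero rows are errors (the offending samples
    are listed).
    """
    values = raw.to_numpy(dtype=float)
    if np.any(values[~np.isnan(values)] < 0):
        bad = raw.index[np.nanmin(values, axis=1) < 0].tolist()
        raise ValueError(f"negative fraction entries in samples: {bad}")
    values = np.nan_to_num(values, nan=0.0)
    totals = values.sum(axis=1)
    zero_rows = raw.index[totals == 0].tolist()
    if zero_rows:
        raise ValueError(f"samples with no measured fractions: {zero_rows}")
    return FractionMatrix(
        values=values / totals[:, None],
        sample_ids=[str(i) for i in raw.index],
        cell_type_names=[str(c) for c in raw.columns],
    )


@dataclass
class CVPlan:
    """Fold assignment for k-fold cross-validation."""

    n_samples: int
    k_folds: int
    assignment: np.ndarray  # per-sample fold index
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, validation indices) for one fold."""
        val = np.flatnonzero(self.assignment == fold)
        trn = np.flatnonzero(self.assignment != fold)
        return trn, val


def make_cv_folds(n: int, k: int = 10, seed: int = 0) -> CVPlan:
    """Seeded shuffle then contiguous chunking; fold sizes differ by <= 1."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return CVPlan(n_samples=n, k_folds=k, assignment=assignment, seed=seed)


def evaluate_predictions(
    true: FractionMatrix,
    estimates: np.ndarray,
    quantiles: tuple[float, ...],
    alpha_mix: float = 0.8,
) -> pd.DataFrame:
    """Metric report at three granularities (long format).

    ``estimates`` has shape (n, K, |quantiles|). Rows cover each
    (cell type, quantile), each cell type on the quantile-averaged
    estimate (quantile = "mean"), and the pooled overall row
    (cell_type = "all"). A constant truth column leaves R (and the
    composite loss) missing for that type, never 0.
    """
    est = np.asarray(estimates, dtype=float)
    n, k, nq = est.shape
    if (n, k) != true.values.shape or nq != len(quantiles):
        raise ValueError("estimate shape does not match truth/quantiles")

    def metric_row(y, yhat, cell_type, quantile):
        e = rmse(y, yhat)
        r = pearson_r(y, yhat) if y.size >= 2 else np.nan
        loss = (
            alpha_mix * (1 - r) + (1 - alpha_mix) * e
            if np.isfinite(r)
            else np.nan
        )
        return {
            "cell_type": cell_type,
            "quantile": quantile,
            "R": r,
            "RMSE": e,
            "loss": loss,
            "n": int(y.size),
        }

    rows = []
    point = est.mean(axis=2)
    for i, ct in enumerate(true.cell_type_names):
        y = true.values[:, i]
        for j, q in enumerate(quantiles):
            rows.append(metric_row(y, est[:, i, j], ct, f"{q:g}"))
        rows.append(metric_row(y, point[:, i], ct, "mean"))
    rows.append(
        metric_row(true.values.ravel(), point.ravel(), "all", "mean")
    )
    return pd.DataFrame(rows)


def overall_pearson_r(true: FractionMatrix, estimates: np.ndarray) -> float:
    """Pooled R between truth and quantile-averaged estimates, all types
    concatenated."""
    point = np.asarray(estimates, dtype=float).mean(axis=2)
    return pearson_r(true.values.ravel(), point.ravel())


def run_cv(
    profiles: np.ndarray,
    fractions: FractionMatrix,
    feature_set: FeatureSet,
    config: ModelConfig,
    plan: CVPlan,
    val_frac: float = 0.1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """k-fold CV: train on each fold's complement, predict the fold.

    ``profiles`` is samples x features, aligned to ``feature_set``.
    Returns the out-of-fold per-quantile estimates in original sample
    order (each sample predicted exactly once) and the pooled report.
    """
    profiles = np.asarray(profiles)
    if profiles.shape[0] != plan.n_samples or (
        fractions.n_samples != plan.n_samples
    ):
        raise ValueError("plan does not match data")
    k_types = fractions.n_types
    oof = np.full((plan.n_samples, k_types, len(config.quantiles)), np.nan)
    for fold in range(plan.k_folds):
        trn, val = plan.fold_indices(fold)
        model = build_model(config, fractions.cell_type_names, feature_set)
        sub_fractions = FractionMatrix(
            values=fractions.values[trn],
            sample_ids=[fractions.sample_ids[i] for i in trn],
            cell_type_names=fractions.cell_type_names,
            row_normalized=fractions.row_normalized,
        )
        train(model, profiles[trn], sub_fractions, val_frac=val_frac)
        oof[val] = predict(model, profiles[val])
    assert not np.isnan(oof).any()
    report = evaluate_predictions(
        fractions, oof, config.quantiles, config.alpha_mix
    )
    return oof, report


def scatter_report(
    true: FractionMatrix,
    estimates: np.ndarray,
    out_path,
) -> pd.DataFrame:
    """Scatter panels (truth vs quantile-averaged estimate) per type + pooled.

    Each panel gets a least-squares line; the returned table carries the
    slope, intercept and R per panel — a slope far from 1 flags estimates
    whose correlation overstates their accuracy. Writes one PNG.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    point = np.asarray(estimates, dtype=float).mean(axis=2)
    panels = [(ct, true.values[:, i], point[:, i])
              for i, ct in enumerate(true.cell_type_names)]
    panels.append(("all", true.values.ravel(), point.ravel()))

    ncol = 4
    nrow = int(np.ceil(len(panels) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow),
                             squeeze=False)
    rows = []
    for ax, (name, y, yhat) in zip(axes.ravel(), panels):
        slope, intercept = np.polyfit(y, yhat, 1)
        r = pearson_r(y, yhat)
        ax.plot(y, yhat, ".", ms=3, alpha=0.5)
        xs = np.array([y.min(), y.max()])
        ax.plot(xs, slope * xs + intercept, "k-", lw=1)
        ax.set_title(f"{name}\nR={r:.3f} slope={slope:.2f}", fontsize=9)
        ax.set_xlabel("true fraction")
        ax.set_ylabel("estimated")
        rows.append({"panel": name, "slope": slope, "intercept": intercept,
                     "R": r})
    for ax in axes.ravel()[len(panels):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return pd.DataFrame(rows)
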