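"""The NNICE estimator: per-(cell type, quantile) linear-activation networks.

Each sub-network maps the fixed gene panel (3000 features by default)
through one densely connected layer of linear units (300 by default) to a
single linear output, with an L2 penalty on the output weight kernel and a
non-negativity constraint on the output bias, enforced by clamping after
every optimiser step. One independent network is trained per (pooled cell
type, quantile) pair — 6 x 5 = 30 by default — each minimising its
quantile's objective (see :mod:`nnice.losses`). The point estimate is the
unweighted average of the five quantile outputs; the (q10, q90) outputs
serve as an uncertainty band. Per-type outputs are deliberately NOT
renormalized across types: each network is an independent regressor, which
sidesteps the multicollinearity that plagues joint softmax heads.

Inputs are normalized as log1p of counts-per-million followed by
per-feature standardisation, with statistics fitted on the training split
only. Everything runs in numpy (the layers are all linear-activation, so
gradients are closed-form); training is exactly reproducible given the
config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import (
    pearson_r,
    rmse,
    training_objective,
    training_objective_grad,
)
from .types import CountMatrix, FeatureSet, FractionMatrix

DEFAULT_QUANTILES = (0.10, 0.25, 0.50, 0.75, 0.90)


@dataclass
class ModelConfig:
    """Hyper-parameters of the deconvolution model (defaults = final model)."""

    n_features: int = 3000
    hidden_units: int = 300
    l2_lambda: float = 1e-4
    l2_on_hidden: bool = False  # paper applies the penalty to the output kernel
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    alpha_mix: float = 0.8
    loss_mode: str = "signed"  # or "literal"
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stopping_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        q = tuple(self.quantiles)
        if any(not 0 < x < 1 for x in q) or any(
            b <= a for a, b in zip(q, q[1:])
        ):
            raise ValueError("quantiles must be strictly increasing, in (0,1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if not 0 <= self.alpha_mix <= 1:
            raise ValueError("alpha_mix must be in [0, 1]")
        if self.loss_mode not in ("signed", "literal"):
            raise ValueError("loss_mode must be 'signed' or 'literal'")
        self.quantiles = q


class QuantileNet:
    """input(F) -> hidden(H, linear) -> output(1, linear), bias >= 0."""

    def __init__(self, cell_type: str, q: float, n_features: int,
                 hidden_units: int, rng: np.random.Generator):
        self.cell_type = cell_type
        self.q = float(q)
        f, h = n_features, hidden_units
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(f), size=(f, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
        self.b2 = 0.0  # satisfies the non-negativity constraint at init

    @property
    def n_parameters(self) -> int:
        f, h = self.W1.shape
        return f * h + h + h + 1

    def forward(self, X: np.ndarray) -> np.ndarray:
        return (X @ self.W1 + self.b1) @ self.w2 + self.b2

    def _forward_hidden(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        H = X @ self.W1 + self.b1
        return H, H @ self.w2 + self.b2

    def backward(self, X: np.ndarray, H: np.ndarray, g_out: np.ndarray,
                 l2_lambda: float, l2_on_hidden: bool):
        """Gradients of (objective + L2 penalty) w.r.t. all parameters."""
        dw2 = H.T @ g_out + 2.0 * l2_lambda * self.w2
        db2 = g_out.sum()
        dH = np.outer(g_out, self.w2)
        dW1 = X.T @ dH
        if l2_on_hidden:
            dW1 += 2.0 * l2_lambda * self.W1
        db1 = dH.sum(axis=0)
        return dW1, db1, dw2, db2

    def get_params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1.copy(), "b1": self.b1.copy(),
                "w2": self.w2.copy(), "b2": np.array(self.b2)}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.W1 = np.array(params["W1"])
        self.b1 = np.array(params["b1"])
        self.w2 = np.array(params["w2"])
        self.b2 = float(params["b2"])


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            g = np.asarray(g, dtype=float)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


@dataclass
class NNICEModel:
    """Bundle of K x |quantiles| quantile networks sharing one feature set."""

    nets: dict[tuple[str, float], QuantileNet]
    feature_set: FeatureSet
    cell_types: list[str]
    config: ModelConfig
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None
    history: dict = field(default_factory=dict)

    @property
    def quantiles(self) -> tuple[float, ...]:
        return self.config.quantiles

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.feature_set.write(directory / "features.txt")
        manifest = {
            "cell_types": self.cell_types,
            "config": dataclasses.asdict(self.config),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        arrays: dict[str, np.ndarray] = {}
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_std"] = self.norm_std
        for i, ((ct, q), net) in enumerate(sorted(self.nets.items())):
            for name, arr in net.get_params().items():
                arrays[f"net{i:03d}__{name}"] = arr
        np.savez(directory / "parameters.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "NNICEModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        cfg_dict = manifest["config"]
        cfg_dict["quantiles"] = tuple(cfg_dict["quantiles"])
        config = ModelConfig(**cfg_dict)
        fs = FeatureSet.read(directory / "features.txt")
        model = build_model(config, manifest["cell_types"], fs)
        data = np.load(directory / "parameters.npz")
        if "norm_mean" in data:
            model.norm_mean = data["norm_mean"]
            model.norm_std = data["norm_std"]
        for i, key in enumerate(sorted(model.nets)):
            model.nets[key].set_params(
                {name: data[f"net{i:03d}__{name}"]
                 for name in ("W1", "b1", "w2", "b2")}
            )
        return model


def normalize_counts(counts: np.ndarray) -> np.ndarray:
    """log1p of counts-per-million, computed row-wise (samples x features)."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    cpm = np.where(totals > 0, counts / np.maximum(totals, 1e-12) * 1e6, 0.0)
    return np.log1p(cpm)


def _as_sample_matrix(profiles, feature_set: FeatureSet) -> np.ndarray:
    """Accept a CountMatrix (genes x samples) or ndarray (samples x features)."""
    if isinstance(profiles, CountMatrix):
        from .feature_select import project_to_features

        return project_to_features(profiles, feature_set).values.T
    arr = np.asarray(profiles)
    if arr.shape[1] != len(feature_set):
        raise ValueError(
            f"profiles have {arr.shape[1]} features, expected {len(feature_set)}"
        )
    return arr


def build_model(
    config: ModelConfig,
    cell_types: list[str],
    feature_set: FeatureSet,
) -> NNICEModel:
    """Create K x |quantiles| networks with independent seeded inits."""
    if len(feature_set) != config.n_features:
        config = dataclasses.replace(config, n_features=len(feature_set))
    nets: dict[tuple[str, float], QuantileNet] = {}
    keys = [(ct, q) for ct in cell_types for q in config.quantiles]
    seeds = np.random.SeedSequence(config.seed).spawn(len(keys))
    for (ct, q), ss in zip(keys, seeds):
        nets[(ct, q)] = QuantileNet(
            ct, q, config.n_features, config.hidden_units,
            np.random.default_rng(ss),
        )
    return NNICEModel(
        nets=nets, feature_set=feature_set, cell_types=list(cell_types),
        config=config,
    )


def train(
    model: NNICEModel,
    train_profiles,
    train_fractions: FractionMatrix,
    val_frac: float = 0.1,
    config: ModelConfig | None = None,
) -> dict:
    """Train every quantile network on (profile -> its type's fraction).

    Input normalization statistics are fitted on the training split only.
    The output bias is clamped to be non-negative after every Adam step.
    Returns the per-net training history (also stored on the model).
    """
    cfg = config or model.config
    X_raw = _as_sample_matrix(train_profiles, model.feature_set)
    n = X_raw.shape[0]
    if train_fractions.n_samples != n:
        raise ValueError("profiles and fractions disagree on sample count")
    Y = train_fractions.to_frame()[model.cell_types].to_numpy()

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    perm = rng.permutation(n)
    n_val = int(round(val_frac * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("training split is empty")

    X_log = normalize_counts(X_raw)
    model.norm_mean = X_log[tr_idx].mean(axis=0)
    model.norm_std = np.maximum(X_log[tr_idx].std(axis=0), 1e-8)
    X = (X_log - model.norm_mean) / model.norm_std
    Xtr, Xval = X[tr_idx], X[val_idx]

    history: dict = {}
    for key in sorted(model.nets):
        ct, q = key
        net = model.nets[key]
        ytr = Y[tr_idx, model.cell_types.index(ct)]
        yval = Y[val_idx, model.cell_types.index(ct)]
        net_rng = np.random.default_rng(
            np.random.SeedSequence(
                [cfg.seed, model.cell_types.index(ct), int(q * 1000)]
            )
        )
        opt = _Adam(
            [net.W1.shape, net.b1.shape, net.w2.shape, ()], cfg.learning_rate
        )
        rows = {"train_loss": [], "val_loss": [], "val_r": [], "val_rmse": []}
        best = (np.inf, net.get_params(), 0)
        for epoch in range(cfg.epochs):
            order = net_rng.permutation(tr_idx.size)
            batch_losses = []
            for start in range(0, order.size, cfg.batch_size):
                b = order[start:start + cfg.batch_size]
                if b.size < 2:
                    continue  # batch metrics need at least two samples
                Xb, yb = Xtr[b], ytr[b]
                Hb, yhat = net._forward_hidden(Xb)
                loss = training_objective(yb, yhat, q, cfg.alpha_mix,
                                          cfg.loss_mode)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss for net {key} at epoch {epoch}"
                    )
                g_out = training_objective_grad(yb, yhat, q, cfg.alpha_mix,
                                                cfg.loss_mode)
                grads = net.backward(Xb, Hb, g_out, cfg.l2_lambda,
                                     cfg.l2_on_hidden)
                dW1, db1, dw2, db2 = opt.step(grads)
                net.W1 -= dW1
                net.b1 -= db1
                net.w2 -= dw2
                net.b2 = max(net.b2 - float(db2), 0.0)  # bias constraint
                batch_losses.append(loss)
            if yval.size >= 2:
                yhat_val = net.forward(Xval)
                vloss = training_objective(yval, yhat_val, q, cfg.alpha_mix,
                                           cfg.loss_mode)
                vr = pearson_r(yval, yhat_val)
                ve = rmse(yval, yhat_val)
            else:
                vloss, vr, ve = np.nan, np.nan, np.nan
            rows["train_loss"].append(float(np.mean(batch_losses)))
            rows["val_loss"].append(float(vloss))
            rows["val_r"].append(float(vr))
            rows["val_rmse"].append(float(ve))
            if np.isfinite(vloss) and vloss < best[0] - 1e-12:
                best = (vloss, net.get_params(), epoch)
            elif (
                np.isfinite(vloss)
                and cfg.early_stopping_patience
                and epoch - best[2] >= cfg.early_stopping_patience
            ):
                break
        if np.isfinite(best[0]):
            net.set_params(best[1])
        history[key] = pd.DataFrame(rows)
    model.history = history
    return history


def predict(model: NNICEModel, bulk_profiles) -> np.ndarray:
    """Per-quantile estimates, shape (n_samples, K, |quantiles|), in [0, 1]."""
    if model.norm_mean is None:
        raise RuntimeError("model has not been trained (no normalization stats)")
    X_raw = _as_sample_matrix(bulk_profiles, model.feature_set)
    X = (normalize_counts(X_raw) - model.norm_mean) / model.norm_std
    out = np.zeros((X.shape[0], len(model.cell_types), len(model.quantiles)))
    for i, ct in enumerate(model.cell_types):
        for j, q in enumerate(model.quantiles):
            out[:, i, j] = model.nets[(ct, q)].forward(X)
    return np.clip(out, 0.0, 1.0)


def aggregate_quantiles(
    estimates: np.ndarray,
    cell_types: list[str],
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    sample_ids: list[str] | None = None,
    renormalize: bool = False,
    sort_quantiles: bool = False,
) -> tuple[FractionMatrix, np.ndarray, np.ndarray]:
    """Average the quantile outputs into a point estimate with a band.

    Returns (point estimates, lower band, upper band) where the band is the
    (lowest-q, highest-q) network output per (sample, type). Quantile
    crossing is reported as-is unless ``sort_quantiles`` is set, in which
    case the outputs are sorted per (sample, type) before banding. If
    ``renormalize``, point-estimate rows are rescaled to sum to one
    (off by default: per-type networks are independent).
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 3 or est.shape[1] != len(cell_types) or (
        est.shape[2] != len(quantiles)
    ):
        raise ValueError("estimates must have shape (n, K, |quantiles|)")
    if sort_quantiles:
        est = np.sort(est, axis=2)
    point = est.mean(axis=2)
    lower, upper = est[:, :, 0], est[:, :, -1]
    if renormalize:
        totals = point.sum(axis=1, keepdims=True)
        point = np.where(totals > 0, point / np.maximum(totals, 1e-12), point)
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(est.shape[0])]
    fm = FractionMatrix(
        values=np.clip(point, 0.0, 1.0),
        sample_ids=sample_ids,
        cell_type_names=list(cell_types),
        row_normalized=False,
    )
    return fm, lower, upper
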