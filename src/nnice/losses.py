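"""Loss functions and metrics for the quantile deconvolution networks.

Two training objectives are provided:

* ``signed`` (default): the classical pinball objective — the tilted loss
  applied to the signed per-sample residual xi_i = y_i - yhat_i, averaged
  over the minibatch, plus ``alpha_mix * (1 - R)`` as a batch-level
  correlation regulariser. Underprediction by the q=0.9 network costs
  9x more than overprediction, so its minimiser is the conditional
  q-quantile and the five networks genuinely bracket the estimate.
* ``literal``: the tilted loss applied to the (non-negative) composite
  batch loss ``alpha*(1-R) + (1-alpha)*RMSE``. Because the composite loss
  is never negative, this reduces exactly to ``q * composite``, so all
  quantile networks optimise proportional objectives; it is retained for
  fidelity experiments.

Analytic gradients with respect to the predictions accompany each loss and
are verified against finite differences in the test suite.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def softmax(z: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax; provided for the legacy multi-output head
    (the final model's sub-networks end in a single linear unit)."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 entries")
    a = yhat - yhat.mean()
    b = y - y.mean()
    na, nb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float((a @ b) / (na * nb))


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error over the minibatch."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("need at least 1 entry")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def custom_loss(y: np.ndarray, yhat: np.ndarray, alpha_mix: float = 0.8) -> float:
    """Composite loss: alpha*(1 - R) + (1 - alpha)*RMSE.

    When R is undefined (a constant vector in the batch) the correlation
    term is dropped and the loss falls back to RMSE alone (logged).
    """
    r = pearson_r(y, yhat)
    e = rmse(y, yhat)
    if np.isnan(r):
        logger.warning("constant batch vector: composite loss fell back to RMSE")
        return e
    return float(alpha_mix * (1.0 - r) + (1.0 - alpha_mix) * e)


def tilted_loss(q: float, xi: np.ndarray | float) -> float:
    """Pinball/tilted loss max(q*xi, (q-1)*xi); elementwise mean for arrays."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    xi = np.asarray(xi, dtype=float)
    return float(np.mean(np.maximum(q * xi, (q - 1.0) * xi)))


def _pearson_grad(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """dR/dyhat for non-constant vectors."""
    a = yhat - yhat.mean()
    b = y - y.mean()
    na, nb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
    r = (a @ b) / (na * nb)
    g = b / (na * nb) - r * a / na**2
    return g - g.mean()  # chain through the centering


def _rmse_grad(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    e = rmse(y, yhat)
    if e == 0.0:
        return np.zeros_like(yhat)
    return (yhat - y) / (y.size * e)


def training_objective(
    y: np.ndarray,
    yhat: np.ndarray,
    q: float,
    alpha_mix: float = 0.8,
    loss_mode: str = "signed",
) -> float:
    """Minibatch objective for the q-quantile network (see module docs)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if loss_mode == "literal":
        return tilted_loss(q, custom_loss(y, yhat, alpha_mix))
    if loss_mode == "signed":
        pin = tilted_loss(q, y - yhat)
        r = pearson_r(y, yhat)
        if np.isnan(r):
            return pin
        return pin + alpha_mix * (1.0 - r)
    raise ValueError(f"unknown loss_mode {loss_mode!r}")


def training_objective_grad(
    y: np.ndarray,
    yhat: np.ndarray,
    q: float,
    alpha_mix: float = 0.8,
    loss_mode: str = "signed",
) -> np.ndarray:
    """Analytic d(objective)/d(yhat), matching :func:`training_objective`."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    n = y.size
    if loss_mode == "literal":
        r = pearson_r(y, yhat)
        if np.isnan(r):
            dL = _rmse_grad(y, yhat)
            L = rmse(y, yhat)
        else:
            dL = -alpha_mix * _pearson_grad(y, yhat) + (1 - alpha_mix) * _rmse_grad(
                y, yhat
            )
            L = custom_loss(y, yhat, alpha_mix)
        scale = q if L >= 0 else q - 1.0
        return scale * dL
    if loss_mode == "signed":
        xi = y - yhat
        g = np.where(xi > 0, -q, 1.0 - q) / n
        g[xi == 0] = 0.0  # subgradient choice at the kink
        r = pearson_r(y, yhat)
        if not np.isnan(r):
            g = g - alpha_mix * _pearson_grad(y, yhat)
        return g
    raise ValueError(f"unknown loss_mode {loss_mode!r}")
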