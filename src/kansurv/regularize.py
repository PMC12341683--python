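"""Sparsity regularization of edge activations and spline coefficients.

The regularizer promotes networks in which only a few edges carry signal:

* the L1 norm of an edge activation is its mean absolute value over the
  training batch, ``|phi|_1 = (1/N_B) sum_s |phi(x^(s))|``;
* a layer's L1 norm ``|Phi|_1`` sums its edges, and the layer entropy
  ``S(Phi)`` is the Shannon entropy of the normalized edge-L1 distribution
  (low entropy = activity concentrated on few edges);
* the spline-coefficient norm ``|c|_1`` is the mean absolute coefficient of
  an edge, summed into the layer norm ``|C|_1``.

The total regularization is

    R = sum_l |Phi_l|_1 + lambda_ent * sum_l S(Phi_l)
        + lambda_coef * sum_l |C_l|_1

and the full training objective adds it to the fast Cox loss as
``l_total = l_cox + lambda * R``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cox import cox_loss_fast, _as_arrays
from .network import KanLayer, KanModel, ActivationEdge, STATE_PRUNED, STATE_SPLINE

__all__ = [
    "activation_l1",
    "coefficient_l1",
    "layer_activation_l1s",
    "layer_entropy",
    "regularization_total",
    "total_loss",
    "RegularizationReport",
    "regularization_report",
]

_ENTROPY_EPS = 1e-12


def activation_l1(edge: ActivationEdge, batch) -> float:
    """Mean absolute post-activation of one edge over the batch."""
    batch = np.asarray(batch, dtype=float).ravel()
    if batch.size == 0:
        raise ValueError("batch must be non-empty")
    return float(np.mean(np.abs(edge.evaluate(batch))))


def coefficient_l1(edge: ActivationEdge) -> float:
    """Mean absolute spline coefficient, ``|c|_1 = (1/(G+k)) sum_i |c_i|``.

    Zero for edges without a live spline (pruned, symbolic, categorical).
    """
    if edge.state != STATE_SPLINE:
        return 0.0
    return float(np.mean(np.abs(edge.spline.coef)))


def layer_activation_l1s(layer: KanLayer, X) -> np.ndarray:
    """Per-edge L1 matrix of shape (n_out, n_in) over the batch ``X``."""
    X = np.asarray(X, dtype=float)
    out = np.zeros((layer.n_out, layer.n_in))
    for j in range(layer.n_out):
        for i in range(layer.n_in):
            if layer.edges[j][i].state == STATE_PRUNED:
                continue
            out[j, i] = activation_l1(layer.edges[j][i], X[:, i])
    return out


def _entropy_from_l1s(l1s: np.ndarray) -> float:
    total = l1s.sum()
    if total <= 0.0:
        return 0.0
    p = l1s.ravel() / total
    nz = p > 0.0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def layer_entropy(layer: KanLayer, X) -> float:
    """Shannon entropy of the normalized per-edge activation-L1 distribution.

    Defined as 0 when the layer L1 vanishes; bounded by log(n_in * n_out).
    """
    return _entropy_from_l1s(layer_activation_l1s(layer, X))


@dataclass
class RegularizationReport:
    """Per-layer breakdown of the regularization terms."""

    edge_l1: list[np.ndarray]  # per layer, (n_out, n_in)
    layer_l1: list[float]  # |Phi_l|_1
    layer_entropy: list[float]  # S(Phi_l)
    layer_coef_l1: list[float]  # |C_l|_1
    batch_size: int
    lam_ent: float
    lam_coef: float
    total: float = field(init=False)

    def __post_init__(self):
        self.total = float(
            sum(self.layer_l1)
            + self.lam_ent * sum(self.layer_entropy)
            + self.lam_coef * sum(self.layer_coef_l1)
        )


def regularization_report(
    model: KanModel, batch, lam_ent: float = 0.0, lam_coef: float = 0.0
) -> RegularizationReport:
    """Evaluate every regularization term on one batch of covariates."""
    X = np.asarray(batch, dtype=float)
    Z = model.normalize_inputs(X)
    edge_l1, layer_l1, entropies, coef_l1 = [], [], [], []
    for layer in model.layers:
        l1s = layer_activation_l1s(layer, Z)
        edge_l1.append(l1s)
        layer_l1.append(float(l1s.sum()))
        entropies.append(_entropy_from_l1s(l1s))
        coef_l1.append(
            float(sum(coefficient_l1(e) for row in layer.edges for e in row))
        )
        Z = layer.forward(Z)
    return RegularizationReport(
        edge_l1, layer_l1, entropies, coef_l1, X.shape[0], lam_ent, lam_coef
    )


def regularization_total(
    model: KanModel, batch, lam_ent: float = 0.0, lam_coef: float = 0.0
) -> float:
    """R = sum_l |Phi_l|_1 + lam_ent sum_l S(Phi_l) + lam_coef sum_l |C_l|_1."""
    return regularization_report(model, batch, lam_ent, lam_coef).total


def total_loss(
    model: KanModel,
    data_batch,
    lam: float = 0.0,
    lam_ent: float = 0.0,
    lam_coef: float = 0.0,
) -> float:
    """Training objective: fast Cox loss plus ``lam`` times the regularizer."""
    X, t, delta = _as_arrays(data_batch)
    theta = model.forward(X)
    loss = cox_loss_fast(theta, t, delta)
    if lam != 0.0:
        loss += lam * regularization_total(model, X, lam_ent, lam_coef)
    return loss
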