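"""Edge and node pruning for automatic feature selection.

Edges whose activation L1 norm (mean absolute output over the full training
set) falls below a threshold are switched to the pruned state and evaluate
to zero.  A hidden node whose incoming or outgoing edges are then all pruned
is removed from the network structurally, cascading until stable.  Input
features whose every outgoing edge is pruned are reported as deselected —
this is the automatic feature-selection mechanism.

When a validation split is available, :func:`auto_prune` scans a log-spaced
grid of thresholds and keeps the one with the best validation C-index,
breaking ties toward the larger threshold (the sparser network).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import concordance_index, _as_arrays
from .exceptions import AllPrunedError
from .network import KanLayer, KanModel, STATE_PRUNED
from .regularize import layer_activation_l1s

__all__ = ["prune", "auto_prune", "deselected_features", "edge_l1_matrices", "PruneReport"]


def edge_l1_matrices(model: KanModel, X) -> list[np.ndarray]:
    """Per-layer (n_out, n_in) activation-L1 matrices over the dataset."""
    Z = model.normalize_inputs(np.asarray(X, dtype=float))
    out = []
    for layer in model.layers:
        out.append(layer_activation_l1s(layer, Z))
        Z = layer.forward(Z)
    return out


def _drop_hidden_node(model: KanModel, layer_idx: int, node: int) -> None:
    """Remove hidden node ``node`` (output ``node`` of layer ``layer_idx``)."""
    below = model.layers[layer_idx]
    above = model.layers[layer_idx + 1]
    below.edges.pop(node)
    for row in above.edges:
        row.pop(node)


def prune(model: KanModel, data, l1_threshold: float) -> KanModel:
    """Prune edges with L1 below ``l1_threshold``; cascade node removal.

    ``data`` supplies the covariate matrix over which the L1 norms are
    computed (the full training set, so decisions are deterministic).
    Because removing an edge shifts the activation distribution of every
    downstream edge, the mark-and-cascade pass repeats with freshly
    computed L1 norms until the network is stable, which makes pruning
    idempotent.  Returns a new model; raises :class:`AllPrunedError` if no
    path to the output survives.
    """
    X = data.X if hasattr(data, "X") else np.asarray(data, dtype=float)
    model = model.copy()
    while True:
        l1s = edge_l1_matrices(model, X)
        marked = False
        for layer, mat in zip(model.layers, l1s):
            for j in range(layer.n_out):
                for i in range(layer.n_in):
                    edge = layer.edges[j][i]
                    if edge.state != STATE_PRUNED and mat[j, i] < l1_threshold:
                        edge.state = STATE_PRUNED
                        marked = True

        # cascade structural removal of dead hidden nodes
        changed = True
        while changed:
            changed = False
            for l in range(len(model.layers) - 1):
                below, above = model.layers[l], model.layers[l + 1]
                for node in range(below.n_out - 1, -1, -1):
                    incoming_dead = all(
                        below.edges[node][i].state == STATE_PRUNED
                        for i in range(below.n_in)
                    )
                    outgoing_dead = all(
                        above.edges[j][node].state == STATE_PRUNED
                        for j in range(above.n_out)
                    )
                    if incoming_dead or outgoing_dead:
                        if below.n_out == 1:
                            raise AllPrunedError(
                                "pruning removed every path to the output node"
                            )
                        _drop_hidden_node(model, l, node)
                        changed = True
        if not marked:
            break

    out_layer = model.layers[-1]
    if all(e.state == STATE_PRUNED for e in out_layer.edges[0]):
        raise AllPrunedError("every edge into the output node is pruned")
    return model


def deselected_features(model: KanModel) -> list[str]:
    """Input features with no surviving outgoing edge."""
    first = model.layers[0]
    dropped = []
    for i, name in enumerate(model.feature_names):
        if all(first.edges[j][i].state == STATE_PRUNED for j in range(first.n_out)):
            dropped.append(name)
    return dropped


@dataclass
class PruneReport:
    threshold: float
    val_cindex: float
    deselected: list[str]
    scanned: list[tuple[float, float]]  # (threshold, val C) for each candidate


def auto_prune(
    model: KanModel,
    train_data,
    val_data,
    n_thresholds: int = 20,
    tie_tol: float = 1e-3,
) -> tuple[KanModel, PruneReport]:
    """Scan a log-spaced threshold grid; keep the best validation C-index.

    Validation C-indices within ``tie_tol`` of the best are treated as tied,
    and ties are broken toward the larger threshold, i.e. the sparser
    network (a sub-resolution gain in C never justifies extra edges).
    Candidates that prune away the whole output path are skipped.
    """
    Xtr, _, _ = _as_arrays(train_data)
    Xv, tv, dv = _as_arrays(val_data)
    l1s = np.concatenate([m.ravel() for m in edge_l1_matrices(model, Xtr)])
    positive = l1s[l1s > 0]
    if positive.size == 0:
        raise AllPrunedError("all edge L1 norms are zero; nothing to retain")
    lo = max(positive.min() * 0.5, positive.max() * 1e-6)
    grid = np.geomspace(lo, positive.max(), n_thresholds)
    candidates = []  # (tau, c, model)
    for tau in grid:
        try:
            cand = prune(model, Xtr, tau)
        except AllPrunedError:
            continue
        c = concordance_index(cand.forward(Xv), tv, dv)
        candidates.append((float(tau), float(c), cand))
    if not candidates:
        raise AllPrunedError("every scanned threshold pruned the output path")
    c_best = max(c for _, c, _ in candidates)
    tau, c, pruned_model = max(
        (cand for cand in candidates if cand[1] >= c_best - tie_tol),
        key=lambda cand: cand[0],
    )
    scanned = [(tau_, c_) for tau_, c_, _ in candidates]
    return pruned_model, PruneReport(tau, c, deselected_features(pruned_model), scanned)
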