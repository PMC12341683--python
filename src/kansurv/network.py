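"""Kolmogorov-Arnold network with learnable B-spline edge activations.

Every edge of the network carries its own univariate activation

    phi(x) = w_b * b(x) + w_s * spline(x),

where ``b`` is a fixed basis function (SiLU by default, identity optionally)
acting as a residual path, and ``spline`` is a learnable B-spline curve.
Node ``j`` of layer ``l + 1`` is the plain sum of its incoming edge
activations, and the network output is the composition of layers.  With a
single output node the scalar the network computes is used as the Cox
log-partial hazard.

The spline part of an edge is defined on a bounded grid; inputs outside the
grid are clamped to the grid boundary before spline evaluation, while the
basis path ``w_b * b(x)`` is evaluated on the raw input so gradients keep
flowing in the tails.

The forward pass, the reverse-mode gradients used for training, and the
JSON checkpoint format are all implemented here in plain numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ShapeError, UnseenCategoryError
from .splines import Spline

__all__ = [
    "silu",
    "ActivationEdge",
    "KanLayer",
    "KanModel",
    "init_model",
    "edge_eval",
    "kan_forward",
]

STATE_SPLINE = "spline"
STATE_SYMBOLIC = "symbolic"
STATE_CATEGORICAL = "categorical_map"
STATE_PRUNED = "pruned"

_CATEGORY_MATCH_TOL = 1e-8


def silu(x: np.ndarray) -> np.ndarray:
    """SiLU basis function x * sigmoid(x), evaluated stably."""
    from scipy.special import expit

    return x * expit(x)


def _silu_grad(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    s = expit(x)
    return s * (1.0 + x * (1.0 - s))


@dataclass
class ActivationEdge:
    """One learnable edge activation phi(x) = w_b b(x) + w_s spline(x).

    The ``state`` field selects which of four evaluation rules governs the
    edge: the trained spline form, a fitted closed-form symbolic expression,
    a finite categorical code->value map, or pruned (identically zero).
    """

    w_b: float = 1.0
    w_s: float = 1.0
    basis_kind: str = "silu"  # "silu" | "identity"
    spline: Spline = field(default_factory=Spline)
    state: str = STATE_SPLINE
    symbolic_fit: object | None = None  # symbolic.SymbolicFit once fitted
    category_map: dict[int, float] | None = None
    category_positions: dict[int, float] | None = None  # code -> encoded input

    def __post_init__(self):
        if self.basis_kind not in ("silu", "identity"):
            raise ConfigurationError(f"unknown basis_kind {self.basis_kind!r}")
        valid = (STATE_SPLINE, STATE_SYMBOLIC, STATE_CATEGORICAL, STATE_PRUNED)
        if self.state not in valid:
            raise ConfigurationError(f"unknown edge state {self.state!r}")

    # -- evaluation -------------------------------------------------------

    def _basis(self, x: np.ndarray) -> np.ndarray:
        return silu(x) if self.basis_kind == "silu" else x

    def _basis_grad(self, x: np.ndarray) -> np.ndarray:
        return _silu_grad(x) if self.basis_kind == "silu" else np.ones_like(x)

    def _clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.spline.lo, self.spline.hi)

    def _categorical_lookup(self, x: np.ndarray) -> np.ndarray:
        positions = np.array(list(self.category_positions.values()))
        codes = np.array(list(self.category_positions.keys()))
        values = np.array([self.category_map[int(c)] for c in codes])
        idx = np.abs(x[:, None] - positions[None, :]).argmin(axis=1)
        mismatch = np.abs(x - positions[idx]) > _CATEGORY_MATCH_TOL
        if mismatch.any():
            bad = x[mismatch][0]
            raise UnseenCategoryError(
                f"input value {bad!r} does not match any trained category position"
            )
        return values[idx]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """phi(x) for a batch of pre-activations."""
        x = np.asarray(x, dtype=float)
        if self.state == STATE_PRUNED:
            return np.zeros_like(x)
        if self.state == STATE_SPLINE:
            return self.w_b * self._basis(x) + self.w_s * self.spline(self._clamp(x))
        if self.state == STATE_SYMBOLIC:
            return self.symbolic_fit(x)
        return self._categorical_lookup(x)

    __call__ = evaluate

    def forward_cache(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Evaluate and keep intermediates needed by :meth:`backward`."""
        x = np.asarray(x, dtype=float)
        if self.state == STATE_SPLINE:
            xc = self._clamp(x)
            B = self.spline.design_matrix(xc)
            s = B @ self.spline.coef
            b = self._basis(x)
            phi = self.w_b * b + self.w_s * s
            inside = (x > self.spline.lo) & (x < self.spline.hi)
            return phi, {"x": x, "xc": xc, "B": B, "s": s, "b": b, "inside": inside}
        phi = self.evaluate(x)
        return phi, {"x": x}

    def backward(self, g: np.ndarray, cache: dict):
        """Return (grads dict or None, grad wrt input x)."""
        if self.state == STATE_PRUNED:
            return None, np.zeros_like(cache["x"])
        if self.state != STATE_SPLINE:
            raise NotImplementedError(
                "gradient training through symbolic or categorical edges is "
                "not supported; train before symbolizing"
            )
        grads = {
            "w_b": float(g @ cache["b"]),
            "w_s": float(g @ cache["s"]),
            "coef": cache["B"].T @ (g * self.w_s),
        }
        sder = np.zeros_like(cache["x"])
        if cache["inside"].any():
            dcoef, subknots = self.spline.derivative_coefficients()
            from scipy.interpolate import BSpline

            D = BSpline.design_matrix(
                cache["xc"][cache["inside"]], subknots, self.spline.degree - 1
            ).toarray()
            sder[cache["inside"]] = D @ dcoef
        gx = g * (self.w_b * self._basis_grad(cache["x"]) + self.w_s * sder)
        return grads, gx

    # -- serialization ----------------------------------------------------

    def copy(self) -> "ActivationEdge":
        return ActivationEdge(
            w_b=self.w_b,
            w_s=self.w_s,
            basis_kind=self.basis_kind,
            spline=self.spline.copy(),
            state=self.state,
            symbolic_fit=self.symbolic_fit,
            category_map=dict(self.category_map) if self.category_map else None,
            category_positions=(
                dict(self.category_positions) if self.category_positions else None
            ),
        )

    def to_dict(self) -> dict:
        d = {
            "w_b": self.w_b,
            "w_s": self.w_s,
            "basis_kind": self.basis_kind,
            "state": self.state,
            "spline": self.spline.to_dict(),
        }
        if self.symbolic_fit is not None:
            d["symbolic_fit"] = self.symbolic_fit.to_dict()
        if self.category_map is not None:
            d["category_map"] = {str(k): v for k, v in self.category_map.items()}
            d["category_positions"] = {
                str(k): v for k, v in self.category_positions.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ActivationEdge":
        fit = None
        if "symbolic_fit" in d:
            from .symbolic import SymbolicFit

            fit = SymbolicFit.from_dict(d["symbolic_fit"])
        cmap = cpos = None
        if "category_map" in d:
            cmap = {int(k): v for k, v in d["category_map"].items()}
            cpos = {int(k): v for k, v in d["category_positions"].items()}
        return cls(
            w_b=d["w_b"],
            w_s=d["w_s"],
            basis_kind=d["basis_kind"],
            spline=Spline.from_dict(d["spline"]),
            state=d["state"],
            symbolic_fit=fit,
            category_map=cmap,
            category_positions=cpos,
        )


class KanLayer:
    """A layer of ``n_out x n_in`` edge activations summed at the nodes."""

    def __init__(self, edges: list[list[ActivationEdge]]):
        if not edges or not edges[0]:
            raise ConfigurationError("layer must have at least one edge")
        n_in = len(edges[0])
        if any(len(row) != n_in for row in edges):
            raise ConfigurationError("ragged edge grid")
        self.edges = edges

    @property
    def n_in(self) -> int:
        return len(self.edges[0])

    @property
    def n_out(self) -> int:
        return len(self.edges)

    def forward(self, X: np.ndarray, with_cache: bool = False):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_in:
            raise ShapeError(f"expected input width {self.n_in}, got {X.shape}")
        Y = np.zeros((X.shape[0], self.n_out))
        cache = [[None] * self.n_in for _ in range(self.n_out)] if with_cache else None
        for j in range(self.n_out):
            for i in range(self.n_in):
                edge = self.edges[j][i]
                if edge.state == STATE_PRUNED:
                    continue
                if with_cache:
                    phi, c = edge.forward_cache(X[:, i])
                    c["phi"] = phi
                    cache[j][i] = c
                else:
                    phi = edge.evaluate(X[:, i])
                Y[:, j] += phi
        return (Y, cache) if with_cache else Y

    def backward(self, gY: np.ndarray, cache, extra_activation_grads=None):
        """Backpropagate through the layer.

        Parameters
        ----------
        gY : (n, n_out) gradient of the loss wrt layer outputs.
        cache : forward cache from ``forward(..., with_cache=True)``.
        extra_activation_grads : optional (n_out, n_in) list grid of extra
            per-sample gradients applied directly to each edge activation
            (used by the activation-magnitude regularizer).

        Returns
        -------
        gX : (n, n_in) gradient wrt the layer input.
        grads : (n_out, n_in) grid of per-edge parameter-gradient dicts.
        """
        n = gY.shape[0]
        gX = np.zeros((n, self.n_in))
        grads = [[None] * self.n_in for _ in range(self.n_out)]
        for j in range(self.n_out):
            for i in range(self.n_in):
                edge = self.edges[j][i]
                if edge.state == STATE_PRUNED or cache[j][i] is None:
                    continue
                g = gY[:, j]
                if extra_activation_grads is not None and extra_activation_grads[j][i] is not None:
                    g = g + extra_activation_grads[j][i]
                edge_grads, gx = edge.backward(g, cache[j][i])
                grads[j][i] = edge_grads
                gX[:, i] += gx
        return gX, grads

    def copy(self) -> "KanLayer":
        return KanLayer([[e.copy() for e in row] for row in self.edges])

    def to_dict(self) -> dict:
        return {"edges": [[e.to_dict() for e in row] for row in self.edges]}

    @classmethod
    def from_dict(cls, d: dict) -> "KanLayer":
        return cls(
            [[ActivationEdge.from_dict(e) for e in row] for row in d["edges"]]
        )


class KanModel:
    """A KAN estimating the Cox log-partial hazard through one output node.

    Inputs are mapped feature-wise through the stored affine normalization
    ``z = scale * x + offset`` (fitted on training data so that z spans the
    spline grid) before entering the first layer.
    """

    def __init__(
        self,
        layers: list[KanLayer],
        feature_names: list[str],
        input_scale: np.ndarray | None = None,
        input_offset: np.ndarray | None = None,
        categorical_features: dict[str, list[int]] | None = None,
    ):
        if not layers:
            raise ConfigurationError("model needs at least one layer")
        for a, b in zip(layers[:-1], layers[1:]):
            if a.n_out != b.n_in:
                raise ConfigurationError("layer shapes do not chain")
        if layers[-1].n_out != 1:
            raise ConfigurationError("the output layer must have a single node")
        if len(feature_names) != layers[0].n_in:
            raise ConfigurationError("feature_names must match the input width")
        self.layers = layers
        self.feature_names = list(feature_names)
        p = layers[0].n_in
        self.input_scale = (
            np.ones(p) if input_scale is None else np.asarray(input_scale, float)
        )
        self.input_offset = (
            np.zeros(p) if input_offset is None else np.asarray(input_offset, float)
        )
        # feature name -> list of raw level codes, for categorical inputs
        self.categorical_features = dict(categorical_features or {})

    @property
    def shape(self) -> list[int]:
        return [self.layers[0].n_in] + [l.n_out for l in self.layers]

    def normalize_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.layers[0].n_in:
            raise ShapeError(
                f"expected {self.layers[0].n_in} features, got shape {X.shape}"
            )
        return X * self.input_scale + self.input_offset

    def forward(self, X: np.ndarray, with_cache: bool = False):
        """Log-partial hazard per row. With ``with_cache`` also returns the
        per-layer forward caches needed for backprop."""
        Z = self.normalize_inputs(X)
        caches = []
        for layer in self.layers:
            if with_cache:
                Z, c = layer.forward(Z, with_cache=True)
                caches.append(c)
            else:
                Z = layer.forward(Z)
        theta = Z[:, 0]
        return (theta, caches) if with_cache else theta

    predict = forward

    # -- flat parameter vector for the optimizer --------------------------

    def _trainable_edges(self):
        for layer in self.layers:
            for row in layer.edges:
                for edge in row:
                    if edge.state == STATE_SPLINE:
                        yield edge

    def parameter_vector(self) -> np.ndarray:
        parts = []
        for e in self._trainable_edges():
            parts.append([e.w_b, e.w_s])
            parts.append(e.spline.coef)
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def set_parameter_vector(self, v: np.ndarray) -> None:
        pos = 0
        for e in self._trainable_edges():
            e.w_b, e.w_s = float(v[pos]), float(v[pos + 1])
            pos += 2
            nb = e.spline.n_basis
            e.spline.coef = np.asarray(v[pos : pos + nb], dtype=float).copy()
            pos += nb
        if pos != v.size:
            raise ShapeError("parameter vector size mismatch")

    def gradient_vector(self, layer_grads) -> np.ndarray:
        parts = []
        for layer, grads in zip(self.layers, layer_grads):
            for j, row in enumerate(layer.edges):
                for i, edge in enumerate(row):
                    if edge.state != STATE_SPLINE:
                        continue
                    g = grads[j][i]
                    if g is None:
                        g = {"w_b": 0.0, "w_s": 0.0, "coef": np.zeros(edge.spline.n_basis)}
                    parts.append([g["w_b"], g["w_s"]])
                    parts.append(g["coef"])
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    # -- serialization -----------------------------------------------------

    def copy(self) -> "KanModel":
        return KanModel(
            [l.copy() for l in self.layers],
            list(self.feature_names),
            self.input_scale.copy(),
            self.input_offset.copy(),
            {k: list(v) for k, v in self.categorical_features.items()},
        )

    def to_dict(self) -> dict:
        return {
            "format": "kansurv-model",
            "version": 1,
            "shape": self.shape,
            "feature_names": self.feature_names,
            "input_scale": self.input_scale.tolist(),
            "input_offset": self.input_offset.tolist(),
            "categorical_features": self.categorical_features,
            "layers": [l.to_dict() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KanModel":
        return cls(
            [KanLayer.from_dict(l) for l in d["layers"]],
            d["feature_names"],
            np.asarray(d["input_scale"], float),
            np.asarray(d["input_offset"], float),
            {k: [int(c) for c in v] for k, v in d.get("categorical_features", {}).items()},
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "KanModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def init_model(
    shape: list[int],
    feature_names: list[str] | None = None,
    *,
    degree: int = 3,
    grid_intervals: int = 5,
    basis_kind: str = "silu",
    input_grid: tuple[float, float] = (-1.0, 1.0),
    hidden_grid: tuple[float, float] = (-3.0, 3.0),
    coef_scale: float = 0.1,
    seed: int = 0,
    input_scale=None,
    input_offset=None,
    categorical_features=None,
) -> KanModel:
    """Build a KAN with w_b = w_s = 1 and small random spline coefficients.

    Input-layer splines live on ``input_grid`` (inputs are normalized there);
    hidden-layer splines use the wider ``hidden_grid`` because node sums are
    not re-normalized during training.
    """
    if len(shape) < 2 or shape[-1] != 1 or any(n < 1 for n in shape):
        raise ConfigurationError(f"invalid shape {shape}: need [n0, ..., 1]")
    rng = np.random.default_rng(seed)
    layers = []
    for l in range(len(shape) - 1):
        lo, hi = input_grid if l == 0 else hidden_grid
        rows = []
        for _ in range(shape[l + 1]):
            row = []
            for _ in range(shape[l]):
                sp = Spline(
                    degree=degree,
                    grid_intervals=grid_intervals,
                    lo=lo,
                    hi=hi,
                    coef=rng.normal(0.0, coef_scale, grid_intervals + degree),
                )
                row.append(ActivationEdge(w_b=1.0, w_s=1.0, basis_kind=basis_kind, spline=sp))
            rows.append(row)
        layers.append(KanLayer(rows))
    names = feature_names or [f"x{i + 1}" for i in range(shape[0])]
    return KanModel(
        layers,
        names,
        input_scale=input_scale,
        input_offset=input_offset,
        categorical_features=categorical_features,
    )


def edge_eval(edge: ActivationEdge, x) -> np.ndarray:
    """Evaluate one edge activation on a batch of pre-activations."""
    return edge.evaluate(x)


def kan_forward(model: KanModel, X) -> np.ndarray:
    """Log-partial hazard for each row of the covariate matrix ``X``."""
    return model.forward(X)
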