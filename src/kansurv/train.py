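"""Training loop: Adam on the regularized fast Cox loss, early stopping on
validation C-index, and cross-validated random hyperparameter search.

The optimizer minimizes the event-averaged fast Cox loss plus
``lam * R`` (regularize.regularization_total); averaging over events keeps
the meaning of ``lam`` independent of dataset size.  Every epoch is one
full-batch gradient step — the datasets this model targets are small enough
that stochastic mini-batching buys nothing, and full batches make the risk
sets of the Cox loss exact within the split.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .cox import concordance_index, cox_loss_fast_with_grad
from .exceptions import ConfigurationError, DivergenceError, UndefinedLossError
from .network import KanModel, init_model
from .regularize import _ENTROPY_EPS

__all__ = ["TrainConfig", "train", "hyperparameter_search", "stratified_event_split"]


@dataclass
class TrainConfig:
    """All knobs of one training run.  ``seed`` fixes every stochastic
    choice: the train/validation split, parameter initialization, and any
    sampling done by the hyperparameter search."""

    shape: list[int] = field(default_factory=lambda: [2, 1])
    grid_intervals: int = 5
    degree: int = 3
    basis_kind: str = "silu"
    learning_rate: float = 0.02
    steps: int = 500
    lam: float = 0.01
    lam_ent: float = 2.0
    lam_coef: float = 0.5
    early_stop_patience: int = 30
    checkpoint_tol: float = 0.0
    val_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0
    search_budget: int = 20
    hidden_grid: tuple = (-3.0, 3.0)
    coef_scale: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.val_fraction <= 0.5):
            raise ConfigurationError("val_fraction must lie in (0, 0.5]")
        for name in ("learning_rate", "lam", "lam_ent", "lam_coef"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_grid"] = list(d["hidden_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "hidden_grid" in d:
            d["hidden_grid"] = tuple(d["hidden_grid"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stratified_event_split(t, delta, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (rest, held-out) stratified on the event indicator
    crossed with duration quartiles."""
    t = np.asarray(t, float)
    delta = np.asarray(delta)
    q = np.searchsorted(np.quantile(t, [0.25, 0.5, 0.75]), t, side="right")
    strata = q * 2 + (delta > 0)
    rest, held = [], []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = idx[rng.permutation(idx.size)]
        k = int(round(idx.size * fraction))
        held.append(idx[:k])
        rest.append(idx[k:])
    return np.sort(np.concatenate(rest)), np.sort(np.concatenate(held))


class _Adam:
    def __init__(self, n_params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, params, grad):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return params - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_and_gradient(model: KanModel, X, t, delta, lam, lam_ent, lam_coef):
    """Event-averaged fast Cox loss + lam * R, with the full parameter
    gradient assembled by backprop through the layers."""
    n_ev = float(np.sum(delta))
    theta, caches = model.forward(X, with_cache=True)
    cox, g_theta = cox_loss_fast_with_grad(theta, t, delta)
    cox /= n_ev
    g_theta = g_theta / n_ev

    n = X.shape[0]
    reg_total = 0.0
    reg_act_grads = []  # per layer: (n_out, n_in) grid of per-sample grads
    coef_grads = []  # per layer: grid of coefficient-space gradients
    if lam > 0.0:
        for layer, cache in zip(model.layers, caches):
            l1s = np.zeros((layer.n_out, layer.n_in))
            for j in range(layer.n_out):
                for i in range(layer.n_in):
                    if cache[j][i] is not None:
                        l1s[j, i] = np.mean(np.abs(cache[j][i]["phi"]))
            A = l1s.sum()
            if A > _ENTROPY_EPS:
                p = l1s / A
                nz = p > 0
                S = float(-np.sum(p[nz] * np.log(p[nz])))
                dS = np.zeros_like(l1s)
                dS[nz] = -(np.log(p[nz]) + S) / A
            else:
                S, dS = 0.0, np.zeros_like(l1s)
            coef_l1 = 0.0
            cgrid = [[None] * layer.n_in for _ in range(layer.n_out)]
            agrid = [[None] * layer.n_in for _ in range(layer.n_out)]
            for j in range(layer.n_out):
                for i in range(layer.n_in):
                    edge = layer.edges[j][i]
                    if cache[j][i] is None:
                        continue
                    if edge.state == "spline":
                        coef_l1 += float(np.mean(np.abs(edge.spline.coef)))
                        cgrid[j][i] = (
                            lam * lam_coef * np.sign(edge.spline.coef)
                            / edge.spline.n_basis
                        )
                    w = lam * (1.0 + lam_ent * dS[j, i])
                    agrid[j][i] = w * np.sign(cache[j][i]["phi"]) / n
            reg_total += l1s.sum() + lam_ent * S + lam_coef * coef_l1
            reg_act_grads.append(agrid)
            coef_grads.append(cgrid)
    loss = cox + lam * reg_total

    # backprop
    gY = g_theta[:, None]
    layer_grads = []
    for li in range(len(model.layers) - 1, -1, -1):
        extra = reg_act_grads[li] if lam > 0.0 else None
        gX, grads = model.layers[li].backward(gY, caches[li], extra)
        if lam > 0.0:
            for j, row in enumerate(grads):
                for i, g in enumerate(row):
                    if g is not None and coef_grads[li][j][i] is not None:
                        g["coef"] = g["coef"] + coef_grads[li][j][i]
        layer_grads.append(grads)
        gY = gX
    layer_grads.reverse()
    return loss, model.gradient_vector(layer_grads)


def train(data, config: TrainConfig, *, val_data=None) -> tuple[KanModel, dict]:
    """Fit a KAN to survival data, returning the best-validation checkpoint.

    The trace dict records per-epoch training loss and validation C-index,
    plus ``best_epoch``.  Training stops early after
    ``early_stop_patience`` epochs without validation improvement, and the
    returned model is the checkpoint with the best validation C-index.

    With a positive ``checkpoint_tol`` any later epoch whose validation
    C-index is within the tolerance of the running best also refreshes the
    checkpoint: among statistically indistinguishable checkpoints the most
    trained one is preferred, because continued optimization keeps shrinking
    regularized (irrelevant) activations at no validation cost.  The
    early-stopping clock still counts from strict improvements only.
    """
    X = np.asarray(data.X, float)
    t = np.asarray(data.t, float)
    delta = np.asarray(data.delta, float)
    rng = np.random.default_rng(config.seed)

    if val_data is None:
        tr_idx, va_idx = stratified_event_split(t, delta, config.val_fraction, rng)
        Xtr, ttr, dtr = X[tr_idx], t[tr_idx], delta[tr_idx]
        Xva, tva, dva = X[va_idx], t[va_idx], delta[va_idx]
    else:
        Xtr, ttr, dtr = X, t, delta
        Xva = np.asarray(val_data.X, float)
        tva = np.asarray(val_data.t, float)
        dva = np.asarray(val_data.delta, float)
    if dtr.sum() == 0 or dva.sum() == 0:
        raise UndefinedLossError("both splits need at least one event")
    if config.shape[0] != X.shape[1]:
        raise ConfigurationError(
            f"config.shape[0]={config.shape[0]} but data has {X.shape[1]} features"
        )

    # per-feature affine normalization to the spline grid, from training rows
    xmin, xmax = Xtr.min(axis=0), Xtr.max(axis=0)
    span = np.where(xmax > xmin, xmax - xmin, 1.0)
    scale = 2.0 / span
    offset = -(xmin + xmax) / span

    model = init_model(
        config.shape,
        feature_names=getattr(data, "feature_names", None),
        degree=config.degree,
        grid_intervals=config.grid_intervals,
        basis_kind=config.basis_kind,
        hidden_grid=tuple(config.hidden_grid),
        coef_scale=config.coef_scale,
        seed=int(rng.integers(2**31 - 1)),
        input_scale=scale,
        input_offset=offset,
        categorical_features=getattr(data, "categorical_levels", None),
    )

    params = model.parameter_vector()
    adam = _Adam(params.size, config.learning_rate)
    trace = {"train_loss": [], "val_cindex": [], "best_epoch": -1}
    best_c, best_params, since_best = -np.inf, params.copy(), 0

    for epoch in range(config.steps):
        loss, grad = _loss_and_gradient(
            model, Xtr, ttr, dtr, config.lam, config.lam_ent, config.lam_coef
        )
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at step {epoch}", step=epoch)
        params = adam.step(params, grad)
        model.set_parameter_vector(params)
        val_c = concordance_index(model.forward(Xva), tva, dva)
        trace["train_loss"].append(float(loss))
        trace["val_cindex"].append(float(val_c))
        if val_c > best_c:
            best_c, best_params, since_best = val_c, params.copy(), 0
            trace["best_epoch"] = epoch
        else:
            if config.checkpoint_tol > 0 and val_c >= best_c - config.checkpoint_tol:
                best_params = params.copy()
                trace["best_epoch"] = epoch
            since_best += 1
            if since_best >= config.early_stop_patience:
                break

    model.set_parameter_vector(best_params)
    return model, trace


def _sample_space(space: dict, rng) -> dict:
    """Draw one configuration from a search space.

    Lists are categorical choices; tuples ``("log", lo, hi)`` and
    ``("lin", lo, hi)`` are continuous ranges.
    """
    out = {}
    for key, spec in space.items():
        if isinstance(spec, list):
            out[key] = spec[rng.integers(len(spec))]
        elif isinstance(spec, tuple) and spec[0] in ("log", "lin"):
            _, lo, hi = spec
            if spec[0] == "log":
                out[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                out[key] = float(rng.uniform(lo, hi))
        else:
            out[key] = spec
    return out


def default_search_space(n_features: int) -> dict:
    return {
        "shape": [[n_features, 1], [n_features, 1, 1], [n_features, 2, 1]],
        "grid_intervals": [3, 4, 5],
        "lam": ("log", 1e-5, 1e-1),
        "learning_rate": ("log", 1e-3, 1e-1),
    }


def hyperparameter_search(
    data,
    space: dict | None = None,
    budget: int = 20,
    seed: int = 0,
    base_config: TrainConfig | None = None,
    cv_folds: int | None = None,
) -> TrainConfig:
    """Random search scored by k-fold cross-validated mean C-index.

    Each candidate is trained on k-1 folds with the held-out fold serving
    both as the early-stopping validation set and the scoring set.  The
    best mean C-index wins; deterministic under ``seed``.
    """
    if budget < 1:
        raise ConfigurationError("budget must be >= 1")
    X = np.asarray(data.X, float)
    t = np.asarray(data.t, float)
    delta = np.asarray(data.delta, float)
    space = space or default_search_space(X.shape[1])
    base = base_config or TrainConfig(shape=[X.shape[1], 1])
    k = cv_folds or base.cv_folds
    rng = np.random.default_rng(seed)

    # stratified folds on the event indicator
    folds = np.empty(t.size, dtype=int)
    for val in (0, 1):
        idx = np.flatnonzero(delta == val)
        idx = idx[rng.permutation(idx.size)]
        folds[idx] = np.arange(idx.size) % k

    class _Slice:
        def __init__(self, sel):
            self.X, self.t, self.delta = X[sel], t[sel], delta[sel]
            self.feature_names = getattr(data, "feature_names", None)
            self.categorical_levels = getattr(data, "categorical_levels", None)

    best = None
    failures = []
    for cand in range(budget):
        overrides = _sample_space(space, rng)
        cfg_dict = base.to_dict()
        cfg_dict.update(overrides)
        cfg_dict["seed"] = int(rng.integers(2**31 - 1))
        try:
            cfg = TrainConfig.from_dict(cfg_dict)
            scores = []
            for f in range(k):
                model, _ = train(
                    _Slice(folds != f), cfg, val_data=_Slice(folds == f)
                )
                sel = folds == f
                scores.append(concordance_index(model.forward(X[sel]), t[sel], delta[sel]))
            mean_c = float(np.mean(scores))
        except Exception as exc:  # noqa: BLE001 - collected and re-raised
            failures.append((cand, overrides, repr(exc)))
            continue
        if best is None or mean_c > best[0]:
            best = (mean_c, cfg)
    if best is None:
        raise ConfigurationError(
            f"all {budget} candidate configurations failed: {failures}"
        )
    return best[1]
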