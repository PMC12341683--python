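"""Proportional-hazards survival-data simulator.

Under a proportional-hazards model with constant baseline hazard h0, the
event time given covariates x is exponential with rate h0 * exp(theta(x)),
so an exact draw is

    T = -ln(U) / (h0 * exp(theta(x))),   U ~ Uniform(0, 1),

the inverse-survival transform of S(t | x) = exp(-h0 e^theta t).  Censoring
times are uniform on [0, c_max], the observed duration is min(T, C) and the
event indicator 1[T <= C].  Covariates are sampled uniformly on [-1, 1] and
two irrelevant noise covariates (excluded from theta) are appended to each
dataset, giving the pruning step something to find.

Four built-in hazard families are provided (gaussian, mixed, euclidean,
complex).  Their exact published definitions are not reproduced here; the
formulas below are documented stand-ins matching the stated family
descriptions and are flagged ``standin: True`` in the formula metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.optimize import brentq

from .cox import CIndexResult, bootstrap_cindex
from .data import FeatureSpec, SurvivalDataset
from .exceptions import ConfigurationError

__all__ = [
    "HazardFormula",
    "simulate_survival",
    "builtin_formula",
    "true_formula_cindex",
    "default_c_max",
]

DEFAULT_BASELINE_HAZARD = 0.01
DEFAULT_NULL_CENSORING = 0.30


def default_c_max(h0: float, censor_fraction: float = DEFAULT_NULL_CENSORING) -> float:
    """Censoring window giving the requested censoring fraction under
    theta = 0, where P(censored) = (1 - exp(-h0 c)) / (h0 c)."""

    def frac(c):
        return (1.0 - np.exp(-h0 * c)) / (h0 * c) - censor_fraction

    return float(brentq(frac, 1e-9 / h0, 1e4 / h0))


@dataclass
class HazardFormula:
    """A symbolic log-partial hazard theta(x) plus simulation parameters."""

    expression: sp.Expr
    variables: list[str]
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    n_noise: int = 2
    c_max: float | None = None  # None -> solve for 30% censoring at theta=0
    name: str = "custom"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline hazard must be positive")
        if self.c_max is None:
            self.c_max = default_c_max(self.baseline_hazard)
        if not np.isfinite(self.c_max) or self.c_max <= 0:
            raise ConfigurationError("c_max must be positive and finite")
        syms = [sp.Symbol(v) for v in self.variables]
        self._fn = sp.lambdify(syms, self.expression, modules=["numpy"])

    def theta(self, X: np.ndarray) -> np.ndarray:
        """Evaluate theta on the relevant covariate columns of X."""
        X = np.asarray(X, dtype=float)
        vals = self._fn(*[X[:, i] for i in range(len(self.variables))])
        return np.broadcast_to(np.asarray(vals, dtype=float), (X.shape[0],)).copy()

    def all_feature_names(self) -> list[str]:
        return list(self.variables) + [f"eps{i + 1}" for i in range(self.n_noise)]


def simulate_survival(formula: HazardFormula, n: int, seed: int = 0) -> SurvivalDataset:
    """Draw ``n`` subjects from the proportional-hazards model.

    Deterministic under ``seed``; noise covariates are drawn from the same
    Uniform[-1, 1] sampler but never enter theta.
    """
    if n < 2:
        raise ConfigurationError("need at least two subjects")
    rng = np.random.default_rng(seed)
    p = len(formula.variables)
    X = rng.uniform(-1.0, 1.0, size=(n, p + formula.n_noise))
    theta = formula.theta(X)
    U = rng.uniform(0.0, 1.0, size=n)
    T = -np.log(U) / (formula.baseline_hazard * np.exp(theta))
    C = rng.uniform(0.0, formula.c_max, size=n)
    t = np.minimum(T, C)
    delta = (T <= C).astype(float)
    names = formula.all_feature_names()
    specs = [FeatureSpec(nm, "numeric") for nm in names]
    return SurvivalDataset(X, t, delta, names, specs)


def _standin(name: str, expr: sp.Expr, variables: list[str]) -> HazardFormula:
    return HazardFormula(
        expr,
        variables,
        name=name,
        metadata={"standin": True, "family": name},
    )


def builtin_formula(name: str) -> HazardFormula:
    """One of the four benchmark hazard families.

    gaussian   radially symmetric bump: no linear signal for CoxPH.
    mixed      additively separable trig + polynomial + linear terms.
    euclidean  distance from the origin in three covariates.
    complex    logarithms, absolute values, and cross-term interactions.

    All four are documented stand-ins (``metadata['standin']``) for the
    originally published formulas.
    """
    x1, x2, x3, x4 = sp.symbols("x1 x2 x3 x4")
    formulas = {
        "gaussian": (2 * sp.exp(-(x1**2 + x2**2)), ["x1", "x2"]),
        "mixed": (sp.sin(sp.pi * x1) + x2**2 + x3, ["x1", "x2", "x3"]),
        "euclidean": (2 * sp.sqrt(x1**2 + x2**2 + x3**2), ["x1", "x2", "x3"]),
        "complex": (
            sp.log(1 + sp.Abs(x1 * x2)) + sp.Abs(x3) * x4**2,
            ["x1", "x2", "x3", "x4"],
        ),
    }
    if name not in formulas:
        raise ConfigurationError(
            f"unknown formula {name!r}; choose from {sorted(formulas)}"
        )
    return _standin(name, *formulas[name])


def true_formula_cindex(
    formula: HazardFormula,
    n_test: int = 10_000,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> CIndexResult:
    """C-index of the true log-partial hazard on a fresh simulated test set.

    This is the performance ceiling: survival time is random, so even the
    generating formula does not reach C = 1, and no proportional-hazards
    ranker can beat it asymptotically.
    """
    data = simulate_survival(formula, n_test, seed=seed)
    theta = formula.theta(data.X)
    if np.all(theta == theta[0]):
        # all scores tied: every admissible pair counts 1/2 by convention
        return CIndexResult(0.5, 0.5, 0.5, 0, seed)
    return bootstrap_cindex(theta, data.t, data.delta, n_bootstrap=n_bootstrap, seed=seed)
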