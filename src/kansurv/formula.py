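"""Extraction of the full symbolic log-partial-hazard formula.

Once every retained edge is in a symbolic or categorical-map state, the
per-edge expressions can be composed through the layer structure into one
closed-form expression for the estimated log-partial hazard.  Because the
partial likelihood is invariant to constant shifts of the score, the
absolute constant in the formula carries no information; what matters is
each term's variation, so terms are ranked by their standard deviation over
a reference dataset (constant terms have sigma = 0 and are dropped from the
ranked report, though they remain in the expression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .exceptions import ConfigurationError
from .network import KanModel, STATE_CATEGORICAL, STATE_PRUNED, STATE_SYMBOLIC

__all__ = ["TermReport", "SymbolicModel", "extract_formula"]


@dataclass
class TermReport:
    expression: sp.Expr
    sigma: float
    provenance: str  # e.g. "layer1:edge(0,2)"


@dataclass
class SymbolicModel:
    """A closed-form log-partial hazard with per-term importance ranking."""

    expression: sp.Expr
    terms: list[TermReport]
    feature_names: list[str]

    def ranked_terms(self) -> list[TermReport]:
        return sorted(
            (t for t in self.terms if t.sigma > 0.0),
            key=lambda t: t.sigma,
            reverse=True,
        )

    def as_text(self) -> str:
        return str(self.expression)

    def as_latex(self) -> str:
        return sp.latex(self.expression)

    def report(self) -> str:
        lines = ["theta(x) =", f"  {self.as_text()}", "", "term importance (sigma):"]
        for t in self.ranked_terms():
            lines.append(f"  {t.sigma:10.4f}  {t.expression}  [{t.provenance}]")
        return "\n".join(lines)


def _edge_expr(edge, input_expr, xsym_raw=None):
    """Sympy expression for one edge applied to ``input_expr``."""
    if edge.state == STATE_SYMBOLIC:
        z = sp.Symbol("_z_")
        return edge.symbolic_fit.sympy_expr(z).subs(z, input_expr)
    if edge.state == STATE_CATEGORICAL:
        # piecewise over the raw level codes of the underlying feature
        var = xsym_raw if xsym_raw is not None else input_expr
        pieces = [
            (sp.Float(v), sp.Eq(var, sp.Integer(code)))
            for code, v in sorted(edge.category_map.items())
        ]
        pieces.append((sp.nan, True))
        return sp.Piecewise(*pieces)
    raise ConfigurationError(
        f"edge in state {edge.state!r}: symbolize the model before extracting"
    )


def extract_formula(model: KanModel, reference_data=None) -> SymbolicModel:
    """Compose per-edge symbolic fits into one expression for theta(x).

    Every retained edge must be in symbolic or categorical-map state.  Term
    standard deviations are evaluated over ``reference_data`` (a covariate
    matrix or a dataset with an ``X`` attribute); without reference data all
    sigmas are reported as 0.
    """
    syms = [sp.Symbol(name) for name in model.feature_names]
    cat_idx = {
        model.feature_names.index(f)
        for f in model.categorical_features
        if f in model.feature_names
    }

    # normalized first-layer inputs in terms of the raw feature symbols
    node_exprs = [
        sp.Float(model.input_scale[i]) * syms[i] + sp.Float(model.input_offset[i])
        for i in range(len(syms))
    ]

    provenance: list[str] | None = None
    for l, layer in enumerate(model.layers):
        new_exprs = []
        contribs = [[None] * layer.n_in for _ in range(layer.n_out)]
        for j in range(layer.n_out):
            total = sp.Integer(0)
            for i in range(layer.n_in):
                edge = layer.edges[j][i]
                if edge.state == STATE_PRUNED:
                    continue
                raw = syms[i] if (l == 0 and i in cat_idx) else None
                expr = _edge_expr(edge, node_exprs[i], xsym_raw=raw)
                contribs[j][i] = expr
                total = total + expr
            new_exprs.append(total)
        node_exprs = new_exprs
        last_contribs, last_l = contribs, l

    # top-level terms: the surviving output-edge contributions, expanded
    terms = []
    for i, expr in enumerate(last_contribs[0]):
        if expr is None:
            continue
        for part in sp.Add.make_args(sp.expand(expr)):
            terms.append((part, f"layer{last_l}:edge(0,{i})"))

    expression = sp.expand(node_exprs[0])

    sigmas = []
    if reference_data is not None:
        X = reference_data.X if hasattr(reference_data, "X") else np.asarray(reference_data, float)
        for part, _ in terms:
            free = sorted(part.free_symbols, key=lambda s: s.name)
            if not free:
                sigmas.append(0.0)
                continue
            cols = [model.feature_names.index(s.name) for s in free]
            fn = sp.lambdify(free, part, modules=["numpy"])
            with np.errstate(all="ignore"):
                vals = np.asarray(fn(*[X[:, c] for c in cols]), dtype=float)
            vals = np.broadcast_to(vals, (X.shape[0],))
            sigmas.append(float(np.nanstd(vals)))
    else:
        sigmas = [0.0] * len(terms)

    reports = [TermReport(p, s, prov) for (p, prov), s in zip(terms, sigmas)]
    return SymbolicModel(expression, reports, list(model.feature_names))
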