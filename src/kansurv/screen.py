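"""High-dimensional preprocessing: univariate Cox screening, correlated-
feature consolidation, and simple deterministic imputation.

These utilities target genomics-style survival data (many features, few
subjects).  Screening keeps features whose one-covariate CoxPH Wald p-value
clears ``alpha``; consolidation merges connected components of highly
correlated features into a single element-wise median feature; imputation
fills missing cells with the per-feature median (numeric) or mode
(categorical) so downstream fits are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .cox import coxph_standard_errors, fit_coxph
from .data import FeatureSpec, SurvivalDataset
from scipy.stats import norm as _norm

__all__ = ["univariate_screen", "consolidate_correlated", "impute_missing"]


def univariate_screen(data: SurvivalDataset, alpha: float):
    """Wald screening by one-covariate CoxPH fits.

    Returns ``(retained, table)`` where ``table`` has one row per feature
    with its coefficient, standard error and p-value.  Constant features are
    skipped with a warning.
    """
    rows = []
    retained = []
    for i, name in enumerate(data.feature_names):
        col = data.X[:, i : i + 1]
        if np.nanstd(col) == 0.0:
            warnings.warn(f"feature {name!r} is constant; skipped by screening")
            continue
        model = fit_coxph((col, data.t, data.delta))
        se = coxph_standard_errors((col, data.t, data.delta), model.beta)
        p = float(2.0 * _norm.sf(abs(model.beta[0]) / se[0]))
        rows.append({"feature": name, "beta": float(model.beta[0]),
                     "se": float(se[0]), "p": p})
        if p <= alpha:
            retained.append(name)
    table = pd.DataFrame(rows, columns=["feature", "beta", "se", "p"])
    return retained, table


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def consolidate_correlated(data: SurvivalDataset, r_threshold: float) -> SurvivalDataset:
    """Merge groups of features with pairwise |Pearson r| >= threshold.

    Groups are connected components of the thresholded correlation graph;
    each is replaced by the element-wise median of its members, with the
    source group recorded in the new feature's spec.  Categorical and
    constant features are never grouped.
    """
    numeric = [
        i for i, s in enumerate(data.feature_specs)
        if s.kind == "numeric" and np.std(data.X[:, i]) > 0
    ]
    if r_threshold > 1.0 or len(numeric) < 2:
        return data
    sub = data.X[:, numeric]
    R = np.corrcoef(sub, rowvar=False)
    uf = _UnionFind(len(numeric))
    for a in range(len(numeric)):
        for b in range(a + 1, len(numeric)):
            if abs(R[a, b]) >= r_threshold:
                uf.union(a, b)
    groups: dict[int, list[int]] = {}
    for a in range(len(numeric)):
        groups.setdefault(uf.find(a), []).append(a)

    cols, names, specs = [], [], []
    consumed = set()
    group_of = {}
    for root, members in groups.items():
        if len(members) > 1:
            for m in members:
                consumed.add(numeric[m])
                group_of[numeric[m]] = root
    emitted_groups = set()
    for i, spec in enumerate(data.feature_specs):
        if i not in consumed:
            cols.append(data.X[:, i])
            names.append(spec.name)
            specs.append(spec)
            continue
        root = group_of[i]
        if root in emitted_groups:
            continue
        emitted_groups.add(root)
        members = [numeric[m] for m in groups[root]]
        member_names = [data.feature_names[m] for m in members]
        med = np.median(data.X[:, members], axis=1)
        name = f"{member_names[0]}_grpmed"
        cols.append(med)
        names.append(name)
        specs.append(FeatureSpec(name, "numeric",
                                 provenance="consolidated-median of group",
                                 source_group=member_names))
    return SurvivalDataset(np.column_stack(cols), data.t, data.delta, names, specs,
                           None)


def impute_missing(data: SurvivalDataset, strategy: str = "median_mode") -> SurvivalDataset:
    """Fill missing cells deterministically; the imputed-cell mask is kept.

    Numeric features take their observed median, categoricals their modal
    code.  A dataset with no missing values is returned unchanged.
    """
    if strategy != "median_mode":
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    mask = np.isnan(data.X)
    if data.missing_mask is not None:
        mask |= data.missing_mask
    if not mask.any():
        return data
    X = data.X.copy()
    for i, spec in enumerate(data.feature_specs):
        m = mask[:, i]
        if not m.any():
            continue
        observed = X[~m, i]
        if observed.size == 0:
            raise ValueError(f"feature {spec.name!r} has no observed values")
        if spec.kind == "numeric":
            X[m, i] = np.median(observed)
        else:
            codes, counts = np.unique(observed, return_counts=True)
            X[m, i] = codes[np.argmax(counts)]
    return replace(data, X=X, missing_mask=mask)
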