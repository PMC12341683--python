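"""Tabular survival data: container, CSV I/O, and label encoding.

A survival dataset is one row per subject: covariates ``X``, a non-negative
duration ``t``, and an event indicator ``delta`` (1 = event observed,
0 = right-censored).  Categorical covariates are label-encoded to integer
codes 0..L-1 on a single input dimension; numeric covariates are affinely
normalized to [-1, 1] with the parameters stored per feature, so the
transform fitted on training data can be applied unchanged to test data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["FeatureSpec", "SurvivalDataset", "load_survival_csv"]


@dataclass
class FeatureSpec:
    """Metadata for one covariate column."""

    name: str
    kind: str  # "numeric" | "categorical"
    levels: list[str] | None = None  # code -> label, for categoricals
    scale: float = 1.0  # z = scale * x_original + offset
    offset: float = 0.0
    provenance: str = "original"
    source_group: list[str] | None = None

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")


@dataclass
class SurvivalDataset:
    """Covariate matrix with durations and event indicators."""

    X: np.ndarray
    t: np.ndarray
    delta: np.ndarray
    feature_names: list[str]
    feature_specs: list[FeatureSpec] = field(default_factory=list)
    missing_mask: np.ndarray | None = None  # True where a cell was imputed/missing

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        n, p = self.X.shape
        if self.t.shape != (n,) or self.delta.shape != (n,):
            raise ConfigurationError("t and delta must match the number of rows")
        if len(self.feature_names) != p:
            raise ConfigurationError("feature_names must match the number of columns")
        if not self.feature_specs:
            self.feature_specs = [FeatureSpec(nm, "numeric") for nm in self.feature_names]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def categorical_levels(self) -> dict[str, list[int]]:
        """Feature name -> list of integer level codes, for categoricals."""
        return {
            s.name: list(range(len(s.levels)))
            for s in self.feature_specs
            if s.kind == "categorical" and s.levels
        }

    def subset(self, idx) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.X[idx],
            self.t[idx],
            self.delta[idx],
            list(self.feature_names),
            list(self.feature_specs),
            None if self.missing_mask is None else self.missing_mask[idx],
        )

    # -- I/O ----------------------------------------------------------------

    def to_dataframe(self, original_scale: bool = True) -> pd.DataFrame:
        """As a DataFrame; numeric columns are de-normalized back to their
        original scale and categoricals decoded to labels when requested."""
        cols = {}
        for i, spec in enumerate(self.feature_specs):
            col = self.X[:, i]
            if original_scale and spec.kind == "numeric":
                col = (col - spec.offset) / spec.scale
            elif original_scale and spec.kind == "categorical":
                col = np.asarray(spec.levels, dtype=object)[col.astype(int)]
            cols[spec.name] = col
        cols["duration"] = self.t
        cols["event"] = self.delta.astype(int)
        return pd.DataFrame(cols)

    def save_csv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {"feature_specs": [asdict(s) for s in self.feature_specs]}
            path.with_suffix(".features.json").write_text(json.dumps(meta, indent=1))


def _check_events(ev: pd.Series):
    vals = pd.to_numeric(ev, errors="coerce")
    bad = vals.isna() | ~vals.isin((0, 1))
    if bad.any():
        rows = [int(r) for r in np.flatnonzero(bad.to_numpy())[:10]]
        raise ConfigurationError(
            f"event column must contain only 0/1; offending rows (0-based): {rows}"
        )
    return vals.to_numpy(dtype=float)


def _check_durations(ts: pd.Series):
    vals = pd.to_numeric(ts, errors="coerce")
    bad = vals.isna() | (vals < 0) | ~np.isfinite(vals)
    if bad.any():
        rows = [int(r) for r in np.flatnonzero(bad.to_numpy())[:10]]
        raise ConfigurationError(
            f"durations must be finite and non-negative; offending rows: {rows}"
        )
    return vals.to_numpy(dtype=float)


def load_survival_csv(
    path,
    duration_col: str = "duration",
    event_col: str = "event",
    categorical_cols: tuple[str, ...] = (),
    normalize: bool = True,
) -> SurvivalDataset:
    """Read a survival CSV, label-encoding categoricals and normalizing
    numeric covariates to [-1, 1] (parameters stored per feature).

    Missing cells are allowed and reported through ``missing_mask``;
    unparseable numeric cells raise with their row indices.
    """
    df = pd.read_csv(path)
    for col in (duration_col, event_col):
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} missing from {path}")
    t = _check_durations(df[duration_col])
    delta = _check_events(df[event_col])
    feat_cols = [c for c in df.columns if c not in (duration_col, event_col)]
    unknown = set(categorical_cols) - set(feat_cols)
    if unknown:
        raise ConfigurationError(f"categorical columns not in file: {sorted(unknown)}")

    X = np.empty((len(df), len(feat_cols)))
    missing = np.zeros_like(X, dtype=bool)
    specs = []
    for i, col in enumerate(feat_cols):
        raw = df[col]
        if col in categorical_cols:
            isna = raw.isna().to_numpy()
            labels = sorted(raw.dropna().astype(str).unique())
            code = {lab: k for k, lab in enumerate(labels)}
            enc = np.array(
                [np.nan if m else code[str(v)] for v, m in zip(raw, isna)], dtype=float
            )
            X[:, i] = enc
            missing[:, i] = isna
            specs.append(FeatureSpec(col, "categorical", levels=labels))
        else:
            vals = pd.to_numeric(raw, errors="coerce")
            unparseable = vals.isna() & raw.notna()
            if unparseable.any():
                rows = [int(r) for r in np.flatnonzero(unparseable.to_numpy())[:10]]
                raise ConfigurationError(
                    f"unparseable numeric cells in column {col!r}, rows {rows}"
                )
            v = vals.to_numpy(dtype=float)
            missing[:, i] = np.isnan(v)
            scale, offset = 1.0, 0.0
            if normalize:
                finite = v[np.isfinite(v)]
                if finite.size and finite.max() > finite.min():
                    scale = 2.0 / (finite.max() - finite.min())
                    offset = -(finite.min() + finite.max()) / (finite.max() - finite.min())
                v = v * scale + offset
            X[:, i] = v
            specs.append(FeatureSpec(col, "numeric", scale=scale, offset=offset))
    return SurvivalDataset(
        X, t, delta, feat_cols, specs, missing if missing.any() else None
    )
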