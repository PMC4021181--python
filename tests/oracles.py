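"""Independent brute-force oracles for the mixed-model computations.

These build the full dense n x n covariance matrix and solve the joint
system directly, deliberately sharing no code with the blockwise
implementation under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from socwage.wage_model import ModelSpec, VarianceComponents


def dense_design(frame: pd.DataFrame, spec: ModelSpec):
    """Full-sample fixed and random effect design matrices.

    Returns (y, X, Z, g, col_meta) where g holds the per-column
    random-effect variance and col_meta tags each Z column with
    (kind, group_code), kind in {minor_int, minor_slope, unit_int,
    unit_slope}.
    """
    age = frame["age"].to_numpy(float) - spec.age_centering
    male = frame["male"].to_numpy(float)
    y = frame["log_wage"].to_numpy(float)
    X = np.column_stack([np.ones(len(frame)), age, male])
    minors = sorted(frame["minor_code"].astype(str).unique())
    units = sorted(frame["unit_code"].astype(str).unique())
    cols, meta = [], []
    for m in minors:
        ind = (frame["minor_code"].astype(str) == m).to_numpy(float)
        cols.append(ind)
        meta.append(("minor_int", m))
        if spec.has_minor_slope:
            cols.append(ind * age)
            meta.append(("minor_slope", m))
    if spec.has_unit:
        for u in units:
            ind = (frame["unit_code"].astype(str) == u).to_numpy(float)
            cols.append(ind)
            meta.append(("unit_int", u))
            if spec.has_unit_slope:
                cols.append(ind * age)
                meta.append(("unit_slope", u))
    Z = np.column_stack(cols)
    return y, X, Z, meta


def _g_of(meta, vc: VarianceComponents) -> np.ndarray:
    return np.array([vc.get(kind) for kind, _ in meta])


def dense_loglik(beta, vc: VarianceComponents, frame: pd.DataFrame,
                 spec: ModelSpec) -> float:
    """Marginal log-likelihood via the full multivariate normal density."""
    y, X, Z, meta = dense_design(frame, spec)
    g = _g_of(meta, vc)
    V = vc.var_resid * np.eye(len(y)) + (Z * g) @ Z.T
    return float(stats.multivariate_normal.logpdf(y, mean=X @ np.asarray(beta),
                                                  cov=V))


def dense_blup(beta, vc: VarianceComponents, frame: pd.DataFrame,
               spec: ModelSpec):
    """Posterior-mean random effects u = G Z' V^{-1} (y - X beta), dense solve.

    Returns (minor, unit) dicts of {"intercept": ., "slope": .} per code.
    """
    y, X, Z, meta = dense_design(frame, spec)
    g = _g_of(meta, vc)
    V = vc.var_resid * np.eye(len(y)) + (Z * g) @ Z.T
    r = y - X @ np.asarray(beta)
    u = g * (Z.T @ np.linalg.solve(V, r))
    minor: dict[str, dict[str, float]] = {}
    unit: dict[str, dict[str, float]] = {}
    for val, (kind, code) in zip(u, meta):
        tier, part = kind.split("_")
        store = minor if tier == "minor" else unit
        entry = store.setdefault(code, {"intercept": 0.0, "slope": 0.0})
        entry["intercept" if part == "int" else "slope"] = float(val)
    return minor, unit


def pearson_r(a, b) -> float:
    """Direct covariance/SD Pearson correlation (no numpy.corrcoef)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum()
                 / np.sqrt((am ** 2).sum() * (bm ** 2).sum()))
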