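"""Ternary deregulation patterns and their mixture-model grouping.

Each gene's response across stromal types is summarized as a vector with
entries -1 (down), 0 (unchanged), +1 (up). Genes are grouped by a finite
mixture of ternary emission components with symmetric flip noise, fitted by
expectation-maximization with Dirichlet-smoothed weights, multiple seeded
restarts, and pruning of empty components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

_TERNARY = (-1, 0, 1)
_EPS_MIN = 1e-6
_EPS_MAX = 2.0 / 3.0 - 1e-6


def ternarize(
    de_tables: dict[str, pd.DataFrame],
    q: float = 0.1,
    stromal_types: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene ternary vector over stromal types from DE tables.

    +1 when padj < q and log2FC > 0, -1 when padj < q and log2FC < 0,
    else 0. Genes absent from a table get 0 there (with a warning).
    """
    if stromal_types is None:
        stromal_types = list(de_tables)
    all_genes: list[str] = []
    seen: set[str] = set()
    for stype in stromal_types:
        for g in de_tables[stype]["feature"]:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)
    out = pd.DataFrame(0, index=all_genes, columns=stromal_types, dtype=int)
    for stype in stromal_types:
        table = de_tables[stype]
        missing = seen - set(table["feature"])
        if missing:
            warnings.warn(
                f"{len(missing)} genes missing from {stype!r} DE table; entries set to 0"
            )
        sig = table.loc[table["padj"] < q]
        up = sig.loc[sig["log2FC"] > 0, "feature"]
        down = sig.loc[sig["log2FC"] < 0, "feature"]
        out.loc[out.index.intersection(up), stype] = 1
        out.loc[out.index.intersection(down), stype] = -1
    return out


@dataclass
class PatternModel:
    """Fitted ternary mixture: patterns, weights, flip noise and posteriors."""

    patterns: pd.DataFrame  # components x stromal types, entries in {-1,0,1}
    weights: np.ndarray
    eps: float
    responsibilities: pd.DataFrame  # genes x components
    assignment: pd.Series  # gene -> component index
    objective: float
    n_iter: int
    converged: bool

    @property
    def m(self) -> int:
        return self.patterns.shape[0]


def _match_counts(y: np.ndarray, pats: np.ndarray) -> np.ndarray:
    """matches[i, m] = number of positions where gene i equals pattern m."""
    return (y[:, None, :] == pats[None, :, :]).sum(axis=2)


def _log_resp(
    y: np.ndarray, pats: np.ndarray, weights: np.ndarray, eps: float
) -> tuple[np.ndarray, float]:
    s = y.shape[1]
    matches = _match_counts(y, pats)
    loglik = matches * np.log1p(-eps) + (s - matches) * np.log(eps / 2.0)
    joint = loglik + np.log(weights)[None, :]
    norm = logsumexp(joint, axis=1)
    return joint - norm[:, None], float(norm.sum())


def _majority_patterns(y: np.ndarray, resp: np.ndarray) -> np.ndarray:
    """Per-component, per-position weighted majority vote over {-1, 0, +1}."""
    n, s = y.shape
    m = resp.shape[1]
    votes = np.empty((3, m, s))
    for vi, v in enumerate(_TERNARY):
        votes[vi] = resp.T @ (y == v)
    return np.array(_TERNARY)[np.argmax(votes, axis=0)]


def fit_pattern_model(
    y: pd.DataFrame | np.ndarray,
    m_max: int = 20,
    eps_init: float = 0.1,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-8,
    dirichlet_alpha: float = 1.1,
) -> PatternModel:
    """EM fit of the ternary-emission mixture with symmetric flip noise.

    Emission per position: probability ``1 - eps`` of matching the component
    pattern, ``eps/2`` for each of the two flips. Weights get a
    Dirichlet(``dirichlet_alpha``) MAP update; components below weight
    ``1/(10*m_max)`` are pruned after convergence and identical patterns are
    merged. The best of ``n_restarts`` seeded restarts (by the smoothed log
    evidence) is returned; the fit is deterministic given ``seed``.
    """
    if isinstance(y, pd.DataFrame):
        genes = list(y.index)
        types = list(y.columns)
        arr = y.to_numpy(dtype=int)
    else:
        arr = np.asarray(y, dtype=int)
        genes = [f"g{i}" for i in range(arr.shape[0])]
        types = [f"t{j}" for j in range(arr.shape[1])]
    if not np.all(np.isin(arr, _TERNARY)):
        raise ValueError("Y must contain only -1, 0, +1")
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    n, s = arr.shape

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, float, int, bool] | None = None
    for _ in range(max(1, n_restarts)):
        if m_max == 1:
            init = arr[[0]] * 0  # placeholder; M-step overwrites immediately
        else:
            idx = rng.choice(n, size=min(m_max, n), replace=False)
            init = arr[idx]
            if len(idx) < m_max:
                extra = rng.choice(_TERNARY, size=(m_max - len(idx), s))
                init = np.vstack([init, extra])
        pats = init.astype(int)
        weights = np.full(m_max, 1.0 / m_max)
        eps = float(np.clip(eps_init, _EPS_MIN, _EPS_MAX))
        prev_obj = -np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            log_r, loglik = _log_resp(arr, pats, weights, eps)
            obj = loglik + (dirichlet_alpha - 1.0) * float(np.sum(np.log(weights)))
            resp = np.exp(log_r)
            # M-step
            counts = resp.sum(axis=0)
            weights = counts + (dirichlet_alpha - 1.0)
            weights = np.maximum(weights, 1e-12)
            weights = weights / weights.sum()
            pats = _majority_patterns(arr, resp)
            matches = _match_counts(arr, pats)
            mismatch = float(np.sum(resp * (s - matches)))
            eps = float(np.clip(mismatch / (n * s), _EPS_MIN, _EPS_MAX))
            if obj - prev_obj < tol * max(1.0, abs(prev_obj)) and n_iter > 1:
                converged = True
                prev_obj = obj
                break
            prev_obj = obj
        if best is None or prev_obj > best[0]:
            best = (prev_obj, pats.copy(), weights.copy(), eps, n_iter, converged)
        if m_max == 1:
            break  # degenerate fit is deterministic; restarts are redundant

    obj, pats, weights, eps, n_iter, converged = best

    # merge identical patterns, then prune negligible components
    merged: dict[tuple[int, ...], float] = {}
    for p, w in zip(pats, weights):
        key = tuple(int(v) for v in p)
        merged[key] = merged.get(key, 0.0) + float(w)
    keys = list(merged)
    weights = np.array([merged[k] for k in keys])
    pats = np.array(keys, dtype=int)
    keep = weights >= 1.0 / (10.0 * m_max)
    if not keep.any():
        keep[np.argmax(weights)] = True
    pats, weights = pats[keep], weights[keep]
    weights = weights / weights.sum()

    log_r, loglik = _log_resp(arr, pats, weights, eps)
    obj = loglik + (dirichlet_alpha - 1.0) * float(np.sum(np.log(weights)))
    resp = np.exp(log_r)
    comp_names = [f"P{m + 1}" for m in range(pats.shape[0])]
    resp_df = pd.DataFrame(resp, index=genes, columns=comp_names)
    assignment = pd.Series(np.argmax(resp, axis=1), index=genes, name="component")
    return PatternModel(
        patterns=pd.DataFrame(pats, index=comp_names, columns=types),
        weights=weights,
        eps=eps,
        responsibilities=resp_df,
        assignment=assignment,
        objective=obj,
        n_iter=n_iter,
        converged=converged,
    )


def em_objective_trace(
    y: np.ndarray,
    m_max: int,
    eps_init: float = 0.1,
    seed: int = 0,
    max_iter: int = 100,
    dirichlet_alpha: float = 1.1,
) -> list[float]:
    """Objective value per EM iteration for a single restart (diagnostics)."""
    arr = np.asarray(y, dtype=int)
    n, s = arr.shape
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(m_max, n), replace=False)
    pats = arr[idx]
    if len(idx) < m_max:
        pats = np.vstack([pats, rng.choice(_TERNARY, size=(m_max - len(idx), s))])
    weights = np.full(m_max, 1.0 / m_max)
    eps = float(np.clip(eps_init, _EPS_MIN, _EPS_MAX))
    trace = []
    for _ in range(max_iter):
        log_r, loglik = _log_resp(arr, pats, weights, eps)
        trace.append(loglik + (dirichlet_alpha - 1.0) * float(np.sum(np.log(weights))))
        resp = np.exp(log_r)
        counts = resp.sum(axis=0)
        weights = np.maximum(counts + dirichlet_alpha - 1.0, 1e-12)
        weights = weights / weights.sum()
        pats = _majority_patterns(arr, resp)
        matches = _match_counts(arr, pats)
        eps = float(np.clip(np.sum(resp * (s - matches)) / (n * s), _EPS_MIN, _EPS_MAX))
    return trace


def pattern_sharing(model: PatternModel) -> pd.DataFrame:
    """Classify each fitted pattern as cell-type-specific, shared, or null."""
    rows = []
    for name, row in model.patterns.iterrows():
        nonzero = row[row != 0]
        if len(nonzero) == 0:
            kind = "null"
        elif len(nonzero) == 1:
            kind = "specific"
        else:
            kind = "shared"
        rows.append((name, kind, ",".join(nonzero.index)))
    return pd.DataFrame(rows, columns=["pattern", "kind", "cell_types"])
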