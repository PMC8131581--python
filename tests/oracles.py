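"""Independent brute-force oracles used to cross-check the package.

Everything here is written with explicit loops straight from the defining
formulas, deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
from scipy import stats as spstats


def size_factors_oracle(mat: np.ndarray) -> list[float]:
    """Median-of-ratios by explicit loops over the definition."""
    n_genes, n_samples = mat.shape
    eligible = [
        g for g in range(n_genes) if all(mat[g][j] > 0 for j in range(n_samples))
    ]
    if not eligible:
        raise ValueError("no all-positive gene")
    geomeans = {}
    for g in eligible:
        log_sum = sum(math.log(mat[g][j]) for j in range(n_samples))
        geomeans[g] = math.exp(log_sum / n_samples)
    factors = []
    for j in range(n_samples):
        ratios = [mat[g][j] / geomeans[g] for g in eligible]
        factors.append(statistics.median(ratios))
    return factors


def bh_oracle(pvals: list[float]) -> list[float]:
    """Step-up adjustment: padj_i = min over tail of m * p_(j) / j."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [math.nan] * m
    for rank_pos, i in enumerate(indexed, start=1):
        tail_min = min(
            m * pvals[indexed[j - 1]] / j for j in range(rank_pos, m + 1)
        )
        adjusted[i] = min(tail_min, 1.0)
    return adjusted


def quantile_normalize_oracle(mat: np.ndarray) -> np.ndarray:
    """Mean of order statistics, ties averaged over their rank span."""
    n, p = mat.shape
    means = [
        sum(sorted(mat[:, j])[r] for j in range(p)) / p for r in range(n)
    ]
    out = np.empty_like(mat, dtype=float)
    for j in range(p):
        order = sorted(range(n), key=lambda i: (mat[i, j], i))
        r = 0
        while r < n:
            r2 = r
            while r2 + 1 < n and mat[order[r2 + 1], j] == mat[order[r], j]:
                r2 += 1
            span_mean = sum(means[r : r2 + 1]) / (r2 - r + 1)
            for k in range(r, r2 + 1):
                out[order[k], j] = span_mean
            r = r2 + 1
    return out


def density_stats_oracle(
    points: np.ndarray, d_c: float
) -> tuple[np.ndarray, np.ndarray, list[int | None]]:
    """O(n^2) double-loop density peaks: Gaussian rho, delta to the nearest
    strictly-denser point (ties broken by earlier index)."""
    n = len(points)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = math.sqrt(sum((points[i] - points[j]) ** 2))
    rho = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                rho[i] += math.exp(-((dist[i, j] / d_c) ** 2))
    delta = np.zeros(n)
    nearest: list[int | None] = [None] * n
    for i in range(n):
        higher = [
            j
            for j in range(n)
            if rho[j] > rho[i] or (rho[j] == rho[i] and j < i)
        ]
        if not higher:
            delta[i] = max(dist[i, j] for j in range(n))
        else:
            best = min(higher, key=lambda j: (dist[i, j], j))
            delta[i] = dist[i, best]
            nearest[i] = best
    return rho, delta, nearest


def lr_join_oracle(
    ligand_calls: dict[str, str],
    receptor_calls_by_type: dict[str, dict[str, str]],
    pairs: list[tuple[str, str]],
) -> set[tuple[str, str, str, str]]:
    """Nested-loop join emitting coherent (ligand, receptor, type, dir)."""
    coherent = set()
    for stype, receptor_calls in receptor_calls_by_type.items():
        for lig, rec in pairs:
            if lig in ligand_calls and rec in receptor_calls:
                if ligand_calls[lig] == receptor_calls[rec]:
                    coherent.add((lig, rec, stype, ligand_calls[lig]))
    return coherent


def quasipoisson_score_oracle(
    y: np.ndarray, in_group_a: np.ndarray, size: np.ndarray
) -> float:
    """Two-sided p for H0: no group effect, via a quasi-Poisson score test.

    Null fit: mu0_j = s_j * sum(y) / sum(s). Score in the group-A direction
    with dispersion estimated from Pearson residuals of the null model.
    """
    mu0 = size * y.sum() / size.sum()
    n = len(y)
    phi = sum((y - mu0) ** 2 / mu0) / (n - 2)
    phi = max(phi, 1e-12)
    sa = mu0[in_group_a].sum()
    st = mu0.sum()
    info = sa - sa**2 / st
    if info <= 0:
        return 1.0
    u = (y[in_group_a] - mu0[in_group_a]).sum()
    z = u / math.sqrt(phi * info)
    return 2.0 * float(spstats.norm.sf(abs(z)))


def equilibrium_distance_oracle(
    k: float, rest: float, q: float, weight: float = 1.0
) -> float:
    """Bisection root of k*w*(d - L) = q / d^2."""

    def balance(d: float) -> float:
        return k * weight * (d - rest) - q / d**2

    lo, hi = 1e-9, rest + 10.0 + 10.0 * q / k
    assert balance(lo) < 0 < balance(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if balance(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
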