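"""Density-peak clustering of z-scored gene profiles.

Implements the decision-graph approach: a Gaussian-kernel local density rho
per gene, the distance delta to the nearest denser gene, cluster centers as
joint (rho, delta) extremes, chain assignment of the remaining genes, halo
(low-density border) exclusion, compactness scoring and hypergeometric
cluster annotation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom, pearsonr

from nicheomics.de import bh_adjust

HALO_LABEL = "noise"


def _distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    return squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))


def auto_dc(dist: np.ndarray, target_mass: float = 0.02) -> float:
    """Kernel width such that the mean Gaussian neighborhood mass is
    ``target_mass`` of the gene count."""
    n = dist.shape[0]
    off = dist[~np.eye(n, dtype=bool)]
    if off.size == 0 or np.all(off == 0):
        return 1.0
    target = target_mass * n
    lo, hi = 1e-9, float(off.max()) * 4 + 1e-9

    def mass(dc: float) -> float:
        return float(np.exp(-((dist / dc) ** 2)).sum() - n) / n

    if mass(hi) < target:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mass(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def density_stats(
    profiles: pd.DataFrame,
    d_c: float | str = "auto",
    target_mass: float = 0.02,
) -> pd.DataFrame:
    """Local density rho, peak distance delta and gamma = rho*delta per gene.

    ``rho_i = sum_{j != i} exp(-(d_ij / d_c)^2)``; ``delta_i`` is the
    distance to the nearest gene of strictly higher density (ties broken by
    stable gene order), and the globally densest gene takes the maximum
    pairwise distance. Columns: rho, delta, gamma, nearest_higher.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two genes")
    dist = _distance_matrix(profiles)
    if isinstance(d_c, str):
        if d_c != "auto":
            raise ValueError(f"unknown d_c mode {d_c!r}")
        d_c = auto_dc(dist, target_mass)
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    n = dist.shape[0]
    kernel = np.exp(-((dist / d_c) ** 2))
    rho = kernel.sum(axis=1) - 1.0  # exclude self term

    # density order: descending rho, stable by input position on ties
    order = np.lexsort((np.arange(n), -rho))
    delta = np.empty(n)
    nearest = np.full(n, -1, dtype=int)
    genes = profiles.index.to_numpy()
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = dist[i].max()
            continue
        higher = order[:pos]
        d_slice = dist[i, higher]
        k = int(np.argmin(d_slice))
        delta[i] = d_slice[k]
        nearest[i] = higher[k]
    out = pd.DataFrame(
        {
            "rho": rho,
            "delta": delta,
            "gamma": rho * delta,
            "nearest_higher": [genes[j] if j >= 0 else None for j in nearest],
        },
        index=profiles.index,
    )
    out.attrs["d_c"] = float(d_c)
    return out


def choose_k(stats: pd.DataFrame, k_max: int | None = None) -> int:
    """Auto K via the largest relative gap in the sorted gamma sequence."""
    gamma = np.sort(stats["gamma"].to_numpy())[::-1]
    limit = len(gamma) - 1 if k_max is None else min(k_max, len(gamma) - 1)
    best_k, best_ratio = 1, -np.inf
    for k in range(1, limit + 1):
        if gamma[k] <= 0:
            return k
        ratio = gamma[k - 1] / gamma[k]
        if ratio > best_ratio:
            best_ratio, best_k = ratio, k
    return best_k


def assign_clusters(stats: pd.DataFrame, k: int | str = "auto") -> pd.DataFrame:
    """Assign every gene to the cluster of its nearest denser neighbor.

    Centers are the top-K genes by gamma; chains of ``nearest_higher``
    pointers terminate at a center because density strictly decreases along
    the processing order.
    """
    n = len(stats)
    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"unknown k mode {k!r}")
        k = choose_k(stats)
    if k > n:
        raise ValueError("K cannot exceed the number of genes")
    gamma = stats["gamma"].to_numpy()
    if k > np.unique(gamma).size:
        raise ValueError("K exceeds the number of distinct gamma values")
    rho = stats["rho"].to_numpy()
    genes = stats.index.to_numpy()
    pos_of = {g: i for i, g in enumerate(genes)}
    center_order = np.lexsort((np.arange(n), -gamma))[:k]
    cluster = np.full(n, -1, dtype=int)
    for cid, i in enumerate(center_order):
        cluster[i] = cid
    density_order = np.lexsort((np.arange(n), -rho))
    for i in density_order:
        if cluster[i] >= 0:
            continue
        parent = stats["nearest_higher"].iloc[i]
        cluster[i] = cluster[pos_of[parent]]
    is_center = np.zeros(n, dtype=bool)
    is_center[center_order] = True
    return pd.DataFrame(
        {"cluster": cluster, "is_center": is_center, "is_halo": False},
        index=stats.index,
    )


def exclude_halo(
    assign: pd.DataFrame,
    stats: pd.DataFrame,
    profiles: pd.DataFrame,
    d_c: float | None = None,
) -> pd.DataFrame:
    """Flag low-density border genes.

    For each cluster the border density is the maximum of ``(rho_i+rho_j)/2``
    over cross-cluster pairs within ``d_c``; members below it become halo.
    Cluster centers are never halo.
    """
    if d_c is None:
        d_c = stats.attrs.get("d_c")
        if d_c is None:
            raise ValueError("d_c not supplied and not recorded on stats")
    dist = _distance_matrix(profiles.loc[assign.index])
    rho = stats["rho"].to_numpy()
    cluster = assign["cluster"].to_numpy()
    n = len(cluster)
    border = np.full(cluster.max() + 1, -np.inf)
    ii, jj = np.where((dist <= d_c) & (cluster[:, None] != cluster[None, :]))
    for i, j in zip(ii, jj):
        avg = 0.5 * (rho[i] + rho[j])
        if avg > border[cluster[i]]:
            border[cluster[i]] = avg
    halo = np.zeros(n, dtype=bool)
    for c in range(border.size):
        if np.isfinite(border[c]):
            halo |= (cluster == c) & (rho < border[c])
    halo &= ~assign["is_center"].to_numpy()
    out = assign.copy()
    out["is_halo"] = halo
    return out


def compactness(
    assign: pd.DataFrame, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster mean profile and mean member correlation with it.

    Halo genes are excluded. Singleton or degenerate (zero-variance mean
    profile) clusters get NaN compactness. Returns (summary, mean profiles).
    """
    core = assign.loc[~assign["is_halo"]]
    rows = []
    mean_profiles = {}
    for cid, members in core.groupby("cluster"):
        mat = profiles.loc[members.index].to_numpy(dtype=float)
        mean_prof = mat.mean(axis=0)
        mean_profiles[cid] = mean_prof
        if mat.shape[0] < 2 or np.std(mean_prof) == 0:
            rows.append((cid, mat.shape[0], np.nan))
            continue
        cors = []
        for row in mat:
            if np.std(row) == 0:
                continue
            cors.append(pearsonr(row, mean_prof)[0])
        comp = float(np.mean(cors)) if cors else np.nan
        rows.append((cid, mat.shape[0], comp))
    summary = pd.DataFrame(rows, columns=["cluster", "size", "compactness"])
    prof_df = pd.DataFrame(mean_profiles, index=profiles.columns).T
    prof_df.index.name = "cluster"
    return summary, prof_df


def cluster_condition_shift(
    cluster_genes: dict[object, list[str]],
    de_tables: dict[str, pd.DataFrame],
    q: float = 0.1,
    member_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean member log2FC per (cluster, stromal type) with a significance star.

    A cell is starred when at least ``member_fraction`` of the cluster's
    members present in the DE table have padj < q.
    """
    rows = []
    for cid, genes in cluster_genes.items():
        gene_set = set(genes)
        for stype, table in de_tables.items():
            sub = table.loc[table["feature"].isin(gene_set)]
            if sub.empty:
                rows.append((cid, stype, np.nan, False, 0))
                continue
            mean_lfc = float(sub["log2FC"].mean())
            frac_sig = float((sub["padj"] < q).mean())
            rows.append((cid, stype, mean_lfc, frac_sig >= member_fraction, len(sub)))
    return pd.DataFrame(
        rows, columns=["cluster", "stromal_type", "mean_log2FC", "significant", "n_genes"]
    )


def annotate_clusters(
    assign: pd.DataFrame,
    sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets per cluster.

    p-values are BH-adjusted within each cluster.
    """
    core = assign.loc[~assign["is_halo"]]
    missing = set(core.index) - universe
    if missing:
        raise ValueError(
            f"universe must contain all cluster genes; missing e.g. {sorted(missing)[:3]}"
        )
    m_total = len(universe)
    rows = []
    for cid, members in core.groupby("cluster"):
        member_set = set(members.index)
        cluster_rows = []
        for name, genes in sets.items():
            in_universe = genes & universe
            if not in_universe:
                warnings.warn(f"gene set {name!r} is disjoint from the universe; skipped")
                continue
            overlap = len(member_set & in_universe)
            p = float(
                hypergeom.sf(overlap - 1, m_total, len(in_universe), len(member_set))
            )
            cluster_rows.append([cid, name, overlap, p])
        if cluster_rows:
            padj = bh_adjust([r[3] for r in cluster_rows])
            for r, adj in zip(cluster_rows, padj):
                rows.append(r + [adj])
    return pd.DataFrame(rows, columns=["cluster", "set", "overlap", "p", "padj"])
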