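"""Synthetic multi-omics data with known ground truth.

Generates every input the analysis pipeline consumes — a negative-binomial
count matrix over stromal populations and conditions, a log-normal secretome
intensity matrix, and a ligand-receptor pair table — together with the
ground-truth cluster memberships, ternary deregulation patterns and planted
coherent ligand-receptor pairs needed to test recovery downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert

DEFAULT_STROMAL_TYPES = (
    "CD31",
    "NESHIGH",
    "NESLOW",
    "NG2",
    "OSX",
    "COLLOW",
    "COLHIGH",
)

NOISE_LABEL = "noise"

_ARCHETYPE_CORR_LIMIT = 0.5


@dataclass
class SimulationConfig:
    """Parameters controlling all synthetic data generation.

    ``seed`` fixes every source of randomness end to end: two runs with the
    same config produce bit-identical outputs.
    """

    n_genes: int = 2000
    n_proteins: int = 300
    stromal_types: tuple[str, ...] = DEFAULT_STROMAL_TYPES
    replicates_per_group: int = 4
    n_clusters: int = 8
    n_patterns: int = 3
    effect_size_lfc: float = 2.0
    dispersion: float = 0.05
    noise_eps: float = 0.05
    noise_gene_fraction: float = 0.1
    profile_noise_sd: float = 0.25
    deregulated_gene_fraction: float = 0.3
    n_deregulated_proteins: int = 40
    n_coherent_pairs: int = 25
    n_decoy_pairs: int = 40
    secretome_sd: float = 0.5
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    conditions: tuple[str, ...] = ("ctrl", "AML")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_proteins", "replicates_per_group", "n_clusters", "n_patterns"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if self.n_clusters > self.n_genes:
            raise ValueError("n_clusters cannot exceed n_genes")
        if not np.isfinite(self.effect_size_lfc):
            raise ValueError("effect_size_lfc must be finite")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0.0 <= self.noise_eps <= 1.0:
            raise ValueError("noise_eps must lie in [0, 1]")
        if len(self.stromal_types) < 2:
            raise ValueError("need at least two stromal types")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi < lo:
            raise ValueError("size_factor_range must be positive and ordered")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    cluster_of_gene: dict[str, object] = field(default_factory=dict)
    pattern_of_gene: dict[str, np.ndarray] = field(default_factory=dict)
    archetypes: pd.DataFrame | None = None
    patterns: pd.DataFrame | None = None
    ligand_shift: dict[str, int] = field(default_factory=dict)
    true_coherent_pairs: set[tuple[str, str, str, str]] = field(default_factory=set)

    def validate(self) -> None:
        for gene, pattern in self.pattern_of_gene.items():
            if not np.all(np.isin(pattern, (-1, 0, 1))):
                raise ValueError(f"pattern for {gene} is not ternary")


def make_archetypes(
    n_types: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """K separable cluster archetype profiles over stromal types.

    The first ``n_types - 1`` archetypes form an orthonormal basis of the
    mean-centered subspace (Helmert construction); further archetypes are
    balanced sign combinations of the basis, keeping every pairwise Pearson
    correlation below 0.5 by construction (anticorrelated profiles count as
    separable: z-profile distance is maximal between v and -v). Rows are
    z-scored (ddof=1).
    """
    if n_types < 2:
        raise ValueError("need at least 2 stromal types")
    basis = helmert(n_types)  # (n_types-1) x n_types, orthonormal, zero-mean rows
    n_basis = basis.shape[0]
    rows = [basis[i] for i in range(min(k, n_basis))]
    # antipodal copies: signed correlation -1, maximally distant z-profiles
    for i in range(n_basis):
        if len(rows) == k:
            break
        rows.append(-basis[i])
    if len(rows) < k:
        # beyond 2*(n_types-1): balanced sign combinations, then seeded random
        def candidates():
            yield -np.ones(n_basis)
            yield np.array([(-1.0) ** i for i in range(n_basis)])
            yield -np.array([(-1.0) ** i for i in range(n_basis)])
            for _ in range(10_000):
                yield rng.choice([-1.0, 1.0], size=n_basis)

        for signs in candidates():
            if len(rows) == k:
                break
            cand = (basis.T @ signs) / np.sqrt(n_basis)
            # signed correlation of unit centered vectors = dot product
            if all(float(cand @ r) < _ARCHETYPE_CORR_LIMIT for r in rows):
                rows.append(cand)
        if len(rows) < k:
            raise RuntimeError("could not construct enough separable archetypes")
    arch = np.vstack(rows[:k])
    # rescale rows to unit sample sd; already mean zero
    arch = arch / arch.std(axis=1, ddof=1, keepdims=True)
    corr = np.corrcoef(arch)
    off = corr[~np.eye(k, dtype=bool)] if k > 1 else np.array([0.0])
    if off.size and np.max(off) >= _ARCHETYPE_CORR_LIMIT:
        raise RuntimeError("archetype construction failed separability check")
    return arch


def make_patterns(n_types: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """M distinct, non-null ternary deregulation patterns."""
    patterns: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    attempts = 0
    while len(patterns) < m:
        n_active = int(rng.integers(1, max(2, n_types // 2) + 1))
        idx = rng.choice(n_types, size=n_active, replace=False)
        vec = np.zeros(n_types, dtype=int)
        vec[idx] = rng.choice([-1, 1], size=n_active)
        key = tuple(vec)
        if key not in seen:
            seen.add(key)
            patterns.append(key)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not generate distinct ternary patterns")
    return np.array(patterns, dtype=int)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"SP{i:0{width}d}" for i in range(1, n + 1)]


def _assign_clusters_and_patterns(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[list[str], GroundTruth]:
    genes = _gene_ids(cfg.n_genes)
    types = list(cfg.stromal_types)
    arch = make_archetypes(len(types), cfg.n_clusters, rng)
    pats = make_patterns(len(types), cfg.n_patterns, rng)
    truth = GroundTruth(
        archetypes=pd.DataFrame(
            arch, index=[f"A{k + 1}" for k in range(cfg.n_clusters)], columns=types
        ),
        patterns=pd.DataFrame(
            pats, index=[f"P{m + 1}" for m in range(cfg.n_patterns)], columns=types
        ),
    )
    n_noise = int(round(cfg.noise_gene_fraction * cfg.n_genes))
    noise_set = set(rng.choice(cfg.n_genes, size=n_noise, replace=False).tolist())
    cluster_idx = rng.integers(0, cfg.n_clusters, size=cfg.n_genes)
    dereg = rng.random(cfg.n_genes) < cfg.deregulated_gene_fraction
    pattern_idx = rng.integers(0, cfg.n_patterns, size=cfg.n_genes)
    zero = np.zeros(len(types), dtype=int)
    for i, g in enumerate(genes):
        truth.cluster_of_gene[g] = NOISE_LABEL if i in noise_set else int(cluster_idx[i])
        truth.pattern_of_gene[g] = pats[pattern_idx[i]].copy() if dereg[i] else zero.copy()
    return genes, truth


def simulate_profiles(
    cfg: SimulationConfig, noise_sd: float | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw z-scored per-gene profiles directly from the archetype model.

    Cluster members are their archetype plus independent Gaussian noise of
    sd ``noise_sd`` (default ``cfg.profile_noise_sd``); noise genes are pure
    standard Gaussian profiles. All rows are re-z-scored (ddof=1).
    """
    if noise_sd is None:
        noise_sd = cfg.profile_noise_sd
    rng = np.random.default_rng(cfg.seed)
    genes, truth = _assign_clusters_and_patterns(cfg, rng)
    types = list(cfg.stromal_types)
    arch = truth.archetypes.to_numpy()
    raw = np.empty((cfg.n_genes, len(types)))
    for i, g in enumerate(genes):
        c = truth.cluster_of_gene[g]
        base = np.zeros(len(types)) if c == NOISE_LABEL else arch[c]
        jitter_sd = 1.0 if c == NOISE_LABEL else noise_sd
        raw[i] = base + rng.normal(0.0, jitter_sd, size=len(types))
    centered = raw - raw.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = centered / sd
    return pd.DataFrame(z, index=genes, columns=types), truth


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Negative-binomial count matrix with embedded clusters and effects.

    Gene ``g`` in cluster ``k`` has a per-stromal-type log2 mean following
    archetype ``A_k`` (plus per-gene profile noise); AML samples multiply the
    mean by ``2**(p_gs * effect_size_lfc)`` where ``p_gs`` is the gene's
    ternary pattern entry for that stromal type. Per-sample size factors are
    log-uniform over ``cfg.size_factor_range``.

    Returns (counts genes x samples, sample metadata, ground truth).
    """
    rng = np.random.default_rng(cfg.seed)
    genes, truth = _assign_clusters_and_patterns(cfg, rng)
    types = list(cfg.stromal_types)
    n_types = len(types)
    arch = truth.archetypes.to_numpy()

    base_log10 = rng.uniform(1.0, 3.0, size=cfg.n_genes)
    profile = np.zeros((cfg.n_genes, n_types))
    for i, g in enumerate(genes):
        c = truth.cluster_of_gene[g]
        if c != NOISE_LABEL:
            profile[i] = arch[c]
        profile[i] = profile[i] + rng.normal(0.0, cfg.profile_noise_sd, size=n_types)
    base_mu = (10.0 ** base_log10)[:, None] * 2.0**profile  # genes x types

    pattern_mat = np.array([truth.pattern_of_gene[g] for g in genes], dtype=float)

    records = []
    for t_idx, stype in enumerate(types):
        for cond in cfg.conditions:
            for rep in range(1, cfg.replicates_per_group + 1):
                records.append((f"{stype}_{cond}_{rep}", stype, cond, rep, t_idx))
    lo, hi = cfg.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(records)))

    counts = np.empty((cfg.n_genes, len(records)), dtype=np.int64)
    for j, (sample_id, stype, cond, rep, t_idx) in enumerate(records):
        mu = base_mu[:, t_idx].copy()
        if cond == "AML":
            mu = mu * 2.0 ** (pattern_mat[:, t_idx] * cfg.effect_size_lfc)
        mu = mu * size_factors[j]
        if cfg.dispersion < 1e-12:
            counts[:, j] = rng.poisson(mu)
        else:
            n_nb = 1.0 / cfg.dispersion
            p_nb = n_nb / (n_nb + mu)
            counts[:, j] = rng.negative_binomial(n_nb, p_nb)

    meta = pd.DataFrame(
        {
            "sample_id": [r[0] for r in records],
            "stromal_type": [r[1] for r in records],
            "condition": [r[2] for r in records],
            "replicate": [r[3] for r in records],
        }
    )
    counts_df = pd.DataFrame(counts, index=genes, columns=meta["sample_id"].tolist())
    counts_df.index.name = "gene"
    return counts_df, meta, truth


def simulate_secretome(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Log-normal secretome intensities plus a ligand-receptor pair table.

    A designated protein subset is shifted by ``+/- effect_size_lfc`` (log2)
    in AML samples. The pair table links shifted ligands to receptor genes
    whose ternary pattern matches the ligand's direction in at least one
    stromal type — those are recorded as planted coherent pairs — plus
    decoy pairs that a correct coherence filter must reject.

    Returns (intensities proteins x samples, sample metadata, L-R pairs,
    updated ground truth).
    """
    rng = np.random.default_rng(cfg.seed + 104729)  # independent stream
    proteins = _protein_ids(cfg.n_proteins)
    types = list(cfg.stromal_types)

    n_dereg = min(cfg.n_deregulated_proteins, cfg.n_proteins)
    dereg_idx = rng.choice(cfg.n_proteins, size=n_dereg, replace=False)
    shifts = np.zeros(cfg.n_proteins, dtype=int)
    shifts[dereg_idx] = rng.choice([-1, 1], size=n_dereg)
    truth.ligand_shift = {p: int(s) for p, s in zip(proteins, shifts)}

    base = rng.normal(10.0, 2.0, size=cfg.n_proteins)
    records = []
    for cond in cfg.conditions:
        for rep in range(1, cfg.replicates_per_group + 1):
            records.append((f"secretome_{cond}_{rep}", cond, rep))
    log2_x = np.empty((cfg.n_proteins, len(records)))
    for j, (sample_id, cond, rep) in enumerate(records):
        mu = base.copy()
        if cond == "AML":
            mu = mu + shifts * cfg.effect_size_lfc
        log2_x[:, j] = rng.normal(mu, cfg.secretome_sd)
    intens = pd.DataFrame(
        2.0**log2_x, index=proteins, columns=[r[0] for r in records]
    )
    intens.index.name = "protein"
    sec_meta = pd.DataFrame(
        {
            "sample_id": [r[0] for r in records],
            "stromal_type": ["BM" for _ in records],
            "condition": [r[1] for r in records],
            "replicate": [r[2] for r in records],
        }
    )

    lr_rows, truth = _build_lr_table(cfg, truth, proteins, shifts, types, rng)
    lr = pd.DataFrame(lr_rows, columns=["ligand", "receptor", "pathway"])
    truth.validate()
    return intens, sec_meta, lr, truth


def _build_lr_table(
    cfg: SimulationConfig,
    truth: GroundTruth,
    proteins: list[str],
    shifts: np.ndarray,
    types: list[str],
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    dereg_proteins = [p for p, s in zip(proteins, shifts) if s != 0]
    flat_proteins = [p for p, s in zip(proteins, shifts) if s == 0]
    genes_by_sign: dict[int, list[str]] = {1: [], -1: []}
    flat_genes: list[str] = []
    for g, pat in truth.pattern_of_gene.items():
        if np.all(pat == 0):
            flat_genes.append(g)
        else:
            for sign in (1, -1):
                if np.any(pat == sign):
                    genes_by_sign[sign].append(g)
    lr_rows: list[tuple[str, str, str]] = []
    used: set[tuple[str, str]] = set()

    lig_cycle = itertools.cycle(dereg_proteins)
    planted = 0
    guard = 0
    while planted < cfg.n_coherent_pairs:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("could not plant enough coherent pairs")
        lig = next(lig_cycle)
        sign = truth.ligand_shift[lig]
        candidates = genes_by_sign[sign]
        if not candidates:
            raise RuntimeError("no receptor genes available for planted direction")
        rec = candidates[int(rng.integers(len(candidates)))]
        if (lig, rec) in used:
            continue
        used.add((lig, rec))
        pathway = f"PW{planted % 5 + 1}"
        lr_rows.append((lig, rec, pathway))
        direction = "up" if sign > 0 else "down"
        pat = truth.pattern_of_gene[rec]
        for t_idx, stype in enumerate(types):
            if pat[t_idx] == sign:
                truth.true_coherent_pairs.add((lig, rec, stype, direction))
        planted += 1

    # decoys: flat ligand + deregulated receptor, deregulated ligand + flat
    # receptor, and incoherent pairs (receptor never matches ligand direction)
    n_decoy = cfg.n_decoy_pairs
    decoy_added = 0
    guard = 0
    while decoy_added < n_decoy and guard < 100_000:
        guard += 1
        kind = decoy_added % 3
        if kind == 0 and flat_proteins and genes_by_sign[1]:
            lig = flat_proteins[int(rng.integers(len(flat_proteins)))]
            rec = genes_by_sign[1][int(rng.integers(len(genes_by_sign[1])))]
        elif kind == 1 and dereg_proteins and flat_genes:
            lig = dereg_proteins[int(rng.integers(len(dereg_proteins)))]
            rec = flat_genes[int(rng.integers(len(flat_genes)))]
        else:
            lig = dereg_proteins[int(rng.integers(len(dereg_proteins)))]
            sign = truth.ligand_shift[lig]
            opposite = [
                g
                for g in genes_by_sign[-sign]
                if not np.any(truth.pattern_of_gene[g] == sign)
            ]
            if not opposite:
                continue
            rec = opposite[int(rng.integers(len(opposite)))]
        if (lig, rec) in used:
            continue
        used.add((lig, rec))
        lr_rows.append((lig, rec, f"PW{decoy_added % 5 + 1}"))
        decoy_added += 1
    return lr_rows, truth


def simulate_ternary(
    patterns: np.ndarray,
    weights: np.ndarray,
    n_genes: int,
    eps: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a ternary matrix from a pattern mixture with symmetric flip noise.

    Each gene picks a component by ``weights``; every entry is then replaced,
    with probability ``eps``, by one of the two other ternary values chosen
    uniformly. Returns (Y, component index per gene).
    """
    patterns = np.asarray(patterns, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if not 0.0 <= eps < 2.0 / 3.0:
        raise ValueError("eps must lie in [0, 2/3)")
    rng = np.random.default_rng(seed)
    z = rng.choice(len(patterns), size=n_genes, p=weights)
    y = patterns[z].copy()
    flip = rng.random(y.shape) < eps
    pick = rng.integers(0, 2, size=y.shape)
    alternatives = {-1: (0, 1), 0: (-1, 1), 1: (-1, 0)}
    original = y.copy()
    for value, (first, second) in alternatives.items():
        here = flip & (original == value)
        y[here] = np.where(pick[here] == 0, first, second)
    return y, z


def perfect_transcriptome_calls(
    truth: GroundTruth, stromal_types: list[str] | tuple[str, ...]
) -> dict[str, pd.DataFrame]:
    """Oracle DE call tables derived straight from the planted patterns."""
    tables: dict[str, pd.DataFrame] = {}
    for t_idx, stype in enumerate(stromal_types):
        rows = []
        for g, pat in truth.pattern_of_gene.items():
            entry = int(pat[t_idx])
            call = "up" if entry > 0 else ("down" if entry < 0 else "ns")
            rows.append((g, call, float(entry)))
        tables[stype] = pd.DataFrame(rows, columns=["feature", "call", "log2FC"])
    return tables


def perfect_secretome_calls(truth: GroundTruth) -> pd.DataFrame:
    """Oracle secretome DE calls derived from the planted ligand shifts."""
    rows = []
    for p, s in truth.ligand_shift.items():
        call = "up" if s > 0 else ("down" if s < 0 else "ns")
        rows.append((p, call, float(s)))
    return pd.DataFrame(rows, columns=["feature", "call", "log2FC"])
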