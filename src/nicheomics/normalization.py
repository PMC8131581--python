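"""Size-factor normalization and profile construction.

Median-of-ratios size factors, regularized log10 transform, per-stromal-type
z-scored mean profiles, and the sample-sample Pearson correlation matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FLAT_SD_THRESHOLD = 1e-12


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Only genes with strictly positive counts in every sample enter the
    pseudo-reference. ``s_j = median_g c_gj / geomean_k(c_gk)``.
    """
    mat = counts.to_numpy(dtype=float)
    eligible = np.all(mat > 0, axis=1)
    if not eligible.any():
        raise ValueError(
            "no gene has strictly positive counts in all samples; "
            "consider adding a pseudocount before computing size factors"
        )
    sub = mat[eligible]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    s = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


def regularized_log(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """``x_gj = log10(c_gj / s_j + pseudocount)``."""
    if (factors <= 0).any():
        raise ValueError("size factors must be strictly positive")
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        missing = factors.index[factors.isna()].tolist()
        raise ValueError(f"missing size factors for samples: {missing}")
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    return pd.DataFrame(
        np.log10(norm + pseudocount), index=counts.index, columns=counts.columns
    )


def z_profiles(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    condition: str = "ctrl",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-scored mean-expression profile across stromal types.

    For each gene: average the regularized expression over replicates within
    each stromal type (restricted to ``condition``), then z-score across
    types with ddof=1. Genes with near-zero variance across types are
    flagged flat (returned mask) and should be excluded from clustering.

    Returns (profiles genes x stromal types, boolean flat flag per gene).
    """
    sel = meta.loc[meta["condition"] == condition]
    if sel.empty:
        raise ValueError(f"no samples with condition {condition!r}")
    types = list(dict.fromkeys(sel["stromal_type"]))
    if len(types) < 2:
        raise ValueError("need at least two stromal types to build profiles")
    means = {}
    for stype in types:
        cols = sel.loc[sel["stromal_type"] == stype, "sample_id"].tolist()
        if not cols:
            raise ValueError(f"stromal type {stype!r} has no samples")
        means[stype] = expr[cols].mean(axis=1)
    prof = pd.DataFrame(means)[types]
    centered = prof.sub(prof.mean(axis=1), axis=0)
    sd = prof.std(axis=1, ddof=1)
    flat = sd < FLAT_SD_THRESHOLD
    safe_sd = sd.where(~flat, 1.0)
    z = centered.div(safe_sd, axis=0)
    z[flat] = 0.0
    flat.name = "flat"
    return z, flat


def sample_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of expression columns (samples).

    Zero-variance samples yield NaN rows/columns (diagonal stays 1).
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = expr.to_numpy(dtype=float)
    sd = mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr[np.ix_(sd == 0, sd == 0)] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.columns, columns=expr.columns)
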