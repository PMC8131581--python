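"""Secretome intensity statistics.

Quantile normalization, log2 transform, and empirical-Bayes moderated
t-tests in which per-protein variances are shrunk toward a prior estimated
by moment matching on the log residual variances (inverse-trigamma solve).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from nicheomics.de import bh_adjust

trigamma = lambda x: polygamma(1, x)  # noqa: E731


def quantile_normalize(x: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the mean-of-order-statistics distribution.

    Ties within a column receive the mean of the reference values over their
    rank span. A single-column matrix is returned unchanged.
    """
    if x.isna().any().any():
        raise ValueError(
            "missing values are not supported; impute or filter before normalizing"
        )
    if x.shape[1] < 2:
        return x.copy()
    mat = x.to_numpy(dtype=float)
    n, p = mat.shape
    means = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(p):
        order = np.argsort(mat[:, j], kind="stable")
        vals = mat[order, j]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and vals[k + 1] == vals[i]:
                k += 1
            out[order[i : k + 1], j] = means[i : k + 1].mean()
            i = k + 1
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def log2_transform(x: pd.DataFrame) -> pd.DataFrame:
    if (x.to_numpy() <= 0).any():
        raise ValueError("intensities must be strictly positive before log2")
    return np.log2(x)


def _trigamma_inverse(target: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = target for y > 0 (Newton iteration)."""
    if target <= 0:
        return np.inf
    if target > 1e7:
        return 1.0 / np.sqrt(target)
    y = 0.5 + 1.0 / target
    for _ in range(100):
        tri = trigamma(y)
        dif = tri * (1.0 - tri / target) / polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-matching estimate of the prior (d0, s0^2) for the variances.

    Matches the mean and variance of ``log(s2)`` against the scaled-F model:
    ``trigamma(d0/2)`` equals the excess variance of the adjusted log
    variances; d0 = inf when there is no excess (fully pooled variances).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        return np.inf, 1e-12
    z = np.log(positive)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    if positive.size < 2:
        return np.inf, float(np.exp(e_mean))
    excess = float(np.var(e, ddof=1)) - float(trigamma(d / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    y0 = _trigamma_inverse(excess)
    d0 = 2.0 * y0
    s0_sq = float(np.exp(e_mean + digamma(y0) - np.log(y0)))
    return d0, s0_sq


def moderated_t(
    x: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    group_col: str = "condition",
    q: float = 0.1,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group empirical-Bayes moderated t-test on a log2 matrix.

    ``d0_override=0`` reduces exactly to the ordinary two-sample pooled t;
    ``d0_override=inf`` pools all variances to the prior value. Returns a DE
    table (log2FC, moderated t, p, BH padj, call) with the fitted prior in
    ``attrs``.
    """
    group_a, group_b = contrast
    cols_a = meta.loc[meta[group_col] == group_a, "sample_id"].tolist()
    cols_b = meta.loc[meta[group_col] == group_b, "sample_id"].tolist()
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = x[cols_a].to_numpy(dtype=float)
    b = x[cols_b].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    d = n1 + n2 - 2
    beta = a.mean(axis=1) - b.mean(axis=1)
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / d
    v = 1.0 / n1 + 1.0 / n2

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_variance_prior(s2, d)
    else:
        d0, s0_sq = fit_variance_prior(s2, d)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = d
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = beta / np.sqrt(s2_post * v)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total)
    padj = bh_adjust(p)
    call = np.full(len(p), "ns", dtype=object)
    sig = padj < q
    call[sig & (beta > 0)] = "up"
    call[sig & (beta < 0)] = "down"
    out = pd.DataFrame(
        {
            "feature": x.index,
            "group_A": group_a,
            "group_B": group_b,
            "log2FC": beta,
            "SE": np.sqrt(s2_post * v),
            "wald_stat": t_stat,
            "p": p,
            "padj": padj,
            "call": call,
            "flag": "",
        }
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["df_residual"] = d
    return out


def dataset_overlap(set_a: set[str], set_b: set[str]) -> float:
    """|A intersect B| / |A|."""
    if not set_a:
        raise ValueError("reference set A is empty; overlap undefined")
    return len(set_a & set_b) / len(set_a)
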