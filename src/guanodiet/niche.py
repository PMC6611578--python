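"""Trophic niche breadth and overlap metrics.

Breadth: Levins (inverse Simpson concentration) and Shannon-Wiener, per
sample, with seasonal aggregation. Group comparisons follow a fixed test
cascade: Shapiro normality on each group, then an F-test (both normal) or
Levene test for variance homogeneity, then a Student or Welch t-test
depending on the variance-test outcome.

Overlap: Morisita-Horn (on arbitrary non-negative weight vectors) and
Pianka (on probability vectors), assembled into symmetric pairwise
matrices over pooled colony x season resource-use vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "levins_breadth",
    "shannon_breadth",
    "seasonal_breadth",
    "CascadeTestResult",
    "breadth_comparison",
    "pool_by_season",
    "morisita_horn",
    "pianka",
    "overlap_matrix",
]


def _as_prob(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("zero vector has no defined breadth")
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("probability vector must sum to 1")
    return p


def levins_breadth(p) -> float:
    """Levins niche breadth ``B = 1 / sum(p_i^2)``; ranges 1..n_items."""
    p = _as_prob(p)
    return float(1.0 / np.sum(p * p))


def shannon_breadth(p) -> float:
    """Shannon-Wiener breadth ``H = -sum(p_i ln p_i)`` in nats; 0*ln0 := 0."""
    p = _as_prob(p)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def seasonal_breadth(values, seasons) -> pd.DataFrame:
    """Mean and sd of per-sample breadth values per season.

    Seasons with no samples are absent from the result, not reported as 0.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "season": list(seasons)})
    if len(df) == 0:
        return pd.DataFrame(columns=["mean", "sd", "n"])
    out = df.groupby("season", sort=False)["value"].agg(mean="mean", sd="std", n="count")
    out["n"] = out["n"].astype(int)
    return out


@dataclass(frozen=True)
class CascadeTestResult:
    shapiro_p_a: float
    shapiro_p_b: float
    variance_test: str  # "F" or "levene"
    variance_p: float
    t_variant: str  # "student" or "welch"
    t_statistic: float
    t_p: float
    alpha: float = 0.05


def breadth_comparison(group_a, group_b, alpha: float = 0.05) -> CascadeTestResult:
    """Two-group comparison with normality-driven test selection.

    Shapiro on each group; if both are non-significant at ``alpha`` the
    variance-equality check is an F-test (two-sided, variance ratio),
    otherwise Levene's test. The location test is a Student t-test when
    variances are homogeneous and Welch otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3 (Shapiro undefined below)")
    sh_a = stats.shapiro(a).pvalue
    sh_b = stats.shapiro(b).pvalue
    if sh_a > alpha and sh_b > alpha:
        var_test = "F"
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
        dfa, dfb = a.size - 1, b.size - 1
        cdf = stats.f.cdf(f, dfa, dfb)
        var_p = 2.0 * min(cdf, 1.0 - cdf)
    else:
        var_test = "levene"
        var_p = stats.levene(a, b, center="median").pvalue
    equal_var = var_p > alpha
    tres = stats.ttest_ind(a, b, equal_var=equal_var)
    return CascadeTestResult(
        shapiro_p_a=float(sh_a),
        shapiro_p_b=float(sh_b),
        variance_test=var_test,
        variance_p=float(var_p),
        t_variant="student" if equal_var else "welch",
        t_statistic=float(tres.statistic),
        t_p=float(tres.pvalue),
        alpha=alpha,
    )


def pool_by_season(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    treatment: str = "wpoo",
) -> pd.DataFrame:
    """Pool per-sample data into colony x season resource-use vectors.

    Parameters
    ----------
    matrix : DataFrame, samples x items
        Raw read counts (``treatment="rra"``) or any non-negative matrix
        whose non-zero pattern defines occurrences (``treatment="wpoo"``).
    metadata : DataFrame indexed by sample id
        Must carry ``colony`` and ``season`` columns for every sample row
        of ``matrix``.
    treatment : {"wpoo", "rra"}
        ``rra``: member counts are summed then normalized. ``wpoo``: item
        weight is proportional to ``sum_k I_ik / n_k`` over member samples
        (each sample contributes its inverse-richness-weighted
        occurrences), normalized.

    Returns a DataFrame of pooled weight vectors (rows ``colony|season``)
    each summing to 1; empty pools are dropped.
    """
    missing = [s for s in matrix.index if s not in metadata.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing[:5]}")
    meta = metadata.loc[matrix.index]
    pools = {}
    for (colony, season), member_ids in matrix.groupby(
        [meta["colony"].values, meta["season"].values]
    ).groups.items():
        sub = matrix.loc[list(member_ids)]
        if treatment == "rra":
            vec = sub.sum(axis=0).to_numpy(dtype=float)
        elif treatment == "wpoo":
            occ = (sub.to_numpy() > 0).astype(float)
            n_k = occ.sum(axis=1)
            keep = n_k > 0
            vec = (occ[keep] / n_k[keep, None]).sum(axis=0)
        else:
            raise ValueError(f"unknown treatment {treatment!r}")
        total = vec.sum()
        if total > 0:
            pools[f"{colony}|{season}"] = vec / total
    return pd.DataFrame.from_dict(pools, orient="index", columns=matrix.columns)


def morisita_horn(x, y) -> float:
    """Morisita-Horn overlap ``C`` in [0, 1] of two weight vectors.

    ``C = 2 sum(x_i y_i) / [(sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y]``
    with ``X = sum(x)``, ``Y = sum(y)``. Scale-invariant in each argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned on the same items")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("weights must be non-negative")
    bx, by = x.sum(), y.sum()
    if bx <= 0 or by <= 0:
        raise ValueError("both vectors must have positive total weight")
    num = 2.0 * np.dot(x, y)
    den = (np.dot(x, x) / bx**2 + np.dot(y, y) / by**2) * bx * by
    val = num / den
    return float(min(max(val, 0.0), 1.0))


def pianka(p, q) -> float:
    """Pianka overlap ``O = sum(p q) / sqrt(sum(p^2) sum(q^2))`` in [0, 1]."""
    p = _as_prob(p)
    q = _as_prob(q)
    if p.shape != q.shape:
        raise ValueError("vectors must be aligned on the same items")
    val = np.dot(p, q) / np.sqrt(np.dot(p, p) * np.dot(q, q))
    return float(min(max(val, 0.0), 1.0))


def overlap_matrix(pools: pd.DataFrame, index_kind: str = "morisita_horn") -> pd.DataFrame:
    """Symmetric pairwise overlap matrix over pooled weight vectors."""
    if len(pools) < 2:
        raise ValueError("need at least two pools")
    if index_kind == "morisita_horn":
        fn = morisita_horn
    elif index_kind == "pianka":
        fn = pianka
    else:
        raise ValueError(f"unknown index {index_kind!r}")
    ids = list(pools.index)
    n = len(ids)
    out = np.eye(n)
    vals = pools.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(vals[i], vals[j])
    return pd.DataFrame(out, index=ids, columns=ids)
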