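"""Statistical primitives shared across pipeline stages.

Two-sample tests used for differential calling:

* Wilcoxon rank-sum — exact permutation enumeration of the rank-sum
  statistic (mid-ranks for ties, two-sided by deviation from the null
  mean) for small samples, scipy's asymptotic normal approximation with
  tie correction otherwise.
* Moderated two-group t — an ordinary two-group linear-model t-statistic
  with optional empirical-Bayes shrinkage of the per-molecule residual
  variances toward a common prior (Smyth-style: the prior degrees of
  freedom d0 and prior variance s0² are moment-estimated from the
  distribution of log sample variances using digamma/trigamma identities
  of the scaled F model).  With moderation off it reduces exactly to the
  pooled-variance two-sample t-test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import special, stats

__all__ = ["rank_sum_test", "moderated_ttest", "trigamma_inverse"]

_EXACT_MAX_N = 12


def rank_sum_test(x, y, exact_max_n: int = _EXACT_MAX_N) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (statistic, pvalue).

    The statistic is the rank sum of ``x`` within the pooled sample
    (mid-ranks for ties).  For n_x + n_y <= ``exact_max_n`` the p-value is
    exact: all C(n, n_x) assignments of the pooled values to the first
    group are enumerated and the two-sided p is the fraction with
    |ranksum − E0| >= the observed deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:nx].sum())
    if nx + ny <= exact_max_n:
        e0 = nx * (nx + ny + 1) / 2.0
        obs_dev = abs(w - e0)
        count = 0
        total = 0
        for comb in combinations(range(nx + ny), nx):
            s = ranks[list(comb)].sum()
            total += 1
            if abs(s - e0) >= obs_dev - 1e-12:
                count += 1
        return w, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


def rank_sum_test_matrix(X_in: np.ndarray, X_out: np.ndarray) -> np.ndarray:
    """Vectorized asymptotic rank-sum p-values, one per column (molecule)."""
    res = stats.mannwhitneyu(
        X_in, X_out, alternative="two-sided", method="asymptotic", axis=0
    )
    return np.asarray(res.pvalue, dtype=float)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    # start from the asymptotic inverse 1/x + 0.5
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match prior (d0, s0²) from sample variances with df residual df.

    Under the hierarchical model s² ~ s0² F(df, d0), z = log s² satisfies
    E z = log s0² + ψ(df/2) − log(df/2) − (ψ(d0/2) − log(d0/2)) and
    Var z = ψ'(df/2) + ψ'(d0/2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(z)
    mean_e = e.mean()
    var_e = ((e - mean_e) ** 2).sum() * n / (n - 1) ** 2  # small-n bias correction
    excess = var_e - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(mean_e))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderated_ttest(
    X_in: np.ndarray, X_out: np.ndarray, moderated: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group (moderated) t per column; returns (logFC, pvalue).

    logFC is the difference of group means.  With ``moderated=False`` the
    p-values equal the pooled-variance two-sample t-test.  With moderation
    on, per-column residual variances are shrunk toward the moment-
    estimated prior: s̃² = (d0·s0² + df·s²)/(d0 + df), t-df = df + d0.
    """
    X_in = np.atleast_2d(np.asarray(X_in, dtype=float))
    X_out = np.atleast_2d(np.asarray(X_out, dtype=float))
    n1, n0 = X_in.shape[0], X_out.shape[0]
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs >= 2 samples")
    df = n1 + n0 - 2
    m1 = X_in.mean(axis=0)
    m0 = X_out.mean(axis=0)
    logfc = m1 - m0
    ss = ((X_in - m1) ** 2).sum(axis=0) + ((X_out - m0) ** 2).sum(axis=0)
    s2 = ss / df
    if moderated:
        d0, s0_sq = _fit_f_dist(s2, df)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = df + d0
    else:
        s2_tilde = s2
        df_total = df
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if np.isinf(df_total):
        pvalue = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvalue = 2.0 * stats.t.sf(np.abs(t), df_total)
    return logfc, pvalue
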