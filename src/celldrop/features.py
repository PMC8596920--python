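"""Dropout-based feature selection (Michaelis–Menten dropout model).

Single-cell expression data show a characteristic relationship between a
molecule's mean expression S and its dropout rate P (fraction of cells with
an exact zero): P = 1 − S/(K + S), the Michaelis–Menten form, where K is
the mean-expression level at which half the cells drop out.  Molecules
whose own Michaelis constant

    K_j = P_j · S_j / (1 − P_j)

sits significantly ABOVE the globally fitted K drop out more often than
their expression level explains — the signature of genuinely bimodal,
subpopulation-specific expression — and are selected as features.

The test is performed on the log scale: z = (log K_j − log K) / se(log K_j),
with the standard error obtained by delta-method propagation of the
binomial error of P_j:  se(P_j) = sqrt(P_j (1 − P_j) / n)  and
d log K_j / dP_j = 1 / (P_j (1 − P_j)), hence

    se(log K_j) = 1 / sqrt(n · P_j · (1 − P_j)).

One-sided upper-tail p-values are BH-adjusted; genes and lncRNAs are fitted
and tested in two independent runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "compute_dropout_stats",
    "gene_specific_K",
    "fit_global_K",
    "select_features",
]


def compute_dropout_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-molecule mean expression S and dropout rate P.

    S is the mean over all cells (zeros included, linear scale); P is the
    fraction of cells in which the value is exactly zero.
    """
    if m.log_transformed:
        raise ValueError("dropout statistics require linear-scale values")
    if m.n_cells == 0:
        raise ValueError("matrix has zero cells")
    S = m.values.mean(axis=0)
    P = (m.values == 0).mean(axis=0)
    return pd.DataFrame({"molecule_id": m.molecule_ids, "S": S, "P": P})


def gene_specific_K(S, P):
    """Molecule-specific Michaelis constant K_j = P·S / (1 − P).

    Vectorized; P must be in [0, 1).  P = 1 is undefined (the caller must
    exclude such molecules) and raises for scalar input.
    """
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("dropout rate P must lie in [0, 1]")
    if S.ndim == 0 and P == 1.0:
        raise ValueError("K_j is undefined at P = 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(P < 1.0, P * S / (1.0 - P), np.inf)
    return float(K) if K.ndim == 0 else K


def _mm_dropout(S: np.ndarray, K: float) -> np.ndarray:
    return 1.0 - S / (K + S)


def fit_global_K(S, P) -> tuple[float, dict]:
    """Least-squares fit of the global Michaelis constant.

    Minimizes sum_j (P_j − (1 − S_j/(K + S_j)))² over molecules with
    S_j > 0 and P_j < 1, in log-K space so positivity is automatic.
    Deterministic given the input.
    """
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    use = (S > 0) & (P < 1.0)
    informative = use & (P > 0)
    if informative.sum() < 2:
        raise ValueError("cannot fit dropout curve: need >= 2 molecules with 0 < P < 1")
    S_fit, P_fit = S[use], P[use]

    # moment start: median of the per-molecule constants
    K0 = float(np.median(gene_specific_K(S[informative], P[informative])))
    K0 = max(K0, 1e-8)

    def resid(logK: np.ndarray) -> np.ndarray:
        return P_fit - _mm_dropout(S_fit, float(np.exp(logK[0])))

    sol = optimize.least_squares(
        resid, x0=[np.log(K0)], xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    K = float(np.exp(sol.x[0]))
    diagnostics = {
        "n_fit": int(use.sum()),
        "sse": float(np.sum(sol.fun**2)),
        "converged": bool(sol.success),
        "start_K": K0,
    }
    return K, diagnostics


def _select_one_kind(values: np.ndarray, ids: list[str], kind: str,
                     fdr_threshold: float, two_sided: bool) -> pd.DataFrame:
    n_cells = values.shape[0]
    S = values.mean(axis=0)
    P = (values == 0).mean(axis=0)
    valid = (S > 0) & (P < 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        K_j = np.where(valid, P * S / np.maximum(1.0 - P, 1e-300), np.nan)
    K_global, _ = fit_global_K(S, P)

    testable = valid & (P > 0)
    se_logK = np.full_like(S, np.nan)
    se_logK[testable] = 1.0 / np.sqrt(n_cells * P[testable] * (1.0 - P[testable]))
    z = np.full_like(S, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z[testable] = (np.log(K_j[testable]) - np.log(K_global)) / se_logK[testable]
    pvalue = np.full_like(S, np.nan)
    if two_sided:
        pvalue[testable] = 2.0 * stats.norm.sf(np.abs(z[testable]))
    else:
        pvalue[testable] = stats.norm.sf(z[testable])
    fdr = np.full_like(S, np.nan)
    if testable.any():
        fdr[testable] = multipletests(pvalue[testable], method="fdr_bh")[1]
    selected = testable & (fdr < fdr_threshold)
    flag = np.where(
        ~valid, np.where(P >= 1.0, "all_dropout", "zero_mean"),
        np.where(P == 0, "no_dropout", "ok"),
    )
    return pd.DataFrame(
        {
            "molecule_id": ids,
            "kind": kind,
            "S": S,
            "P": P,
            "K_j": K_j,
            "global_K": K_global,
            "se_logK": se_logK,
            "z": z,
            "pvalue": pvalue,
            "fdr": fdr,
            "selected": selected,
            "flag": flag,
        }
    )


def select_features(
    m: ExpressionMatrix,
    fdr_threshold: float = 0.01,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Dropout-model feature selection; one independent run per molecule kind.

    Returns a per-molecule table in the input molecule order with columns
    ``molecule_id, kind, S, P, K_j, global_K, se_logK, z, pvalue, fdr,
    selected, flag``.  Molecules with S = 0 or P = 1 are flagged and never
    selected; molecules with P = 0 have an undefined (−inf) log K_j and are
    likewise reported unselected.
    """
    if m.log_transformed:
        raise ValueError("feature selection requires linear-scale values")
    parts = []
    for kind in pd.unique(m.molecule_kind):
        cols = np.flatnonzero(m.molecule_kind == kind)
        sub = _select_one_kind(
            m.values[:, cols],
            [m.molecule_ids[i] for i in cols],
            str(kind),
            fdr_threshold,
            two_sided,
        )
        sub.index = cols
        parts.append(sub)
    out = pd.concat(parts).sort_index().reset_index(drop=True)
    return out
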