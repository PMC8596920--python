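"""Differential dropout and differential expression calling per dropout cluster.

For each dropout cluster, cells split into two groups — the cluster and all
remaining cells (DBSCAN noise cells included in the remainder) — and every
molecule is tested on two axes:

* differential dropout (DDG / DDLR): the dropout rate differs between the
  groups by strictly more than 0.5;
* differential expression (DEG / DELR): |log2 fold change| strictly above 1
  with a two-sided p-value below 0.05 (Wilcoxon rank-sum by default, Welch
  t optional), on the log2(x+1) scale, no multiple-testing correction by
  default (BH behind a flag).

Flagged molecules from all clusters are pooled with deduplication into the
differential-molecule set that seeds the co-expression network.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .stats import rank_sum_test, rank_sum_test_matrix

__all__ = [
    "dropout_rate_by_group",
    "call_differential_dropout",
    "call_differential_expression",
    "analyze_cluster",
    "pool_differential_molecules",
]

DROPOUT_FLAG = "DD"
EXPRESSION_FLAG = "DE"


def _split_mask(m: ExpressionMatrix, in_cells) -> np.ndarray:
    in_cells = list(in_cells)
    if not in_cells:
        raise ValueError("in_cells is empty")
    idx = m.cell_index(in_cells)
    mask = np.zeros(m.n_cells, dtype=bool)
    mask[idx] = True
    if mask.all():
        raise ValueError("in_cells covers every cell; complement is empty")
    return mask


def dropout_rate_by_group(m: ExpressionMatrix, in_cells) -> pd.DataFrame:
    """Per-molecule dropout rate inside and outside a cell group.

    The dropout rate is the fraction of exact zeros, so it is invariant to
    any strictly positive rescaling and valid on linear or log2(x+1) values.
    """
    mask = _split_mask(m, in_cells)
    zeros = m.values == 0
    rate_in = zeros[mask].mean(axis=0)
    rate_out = zeros[~mask].mean(axis=0)
    return pd.DataFrame(
        {"molecule_id": m.molecule_ids, "rate_in": rate_in, "rate_out": rate_out}
    )


def call_differential_dropout(rates: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Flag molecules with |rate_in − rate_out| strictly above the threshold."""
    out = rates.copy()
    out["dropout_diff"] = (out["rate_in"] - out["rate_out"]).abs()
    out["dd_flag"] = out["dropout_diff"] > threshold
    return out


def call_differential_expression(
    m: ExpressionMatrix,
    in_cells,
    logfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    test: str = "wilcoxon",
    adjust: bool = False,
) -> pd.DataFrame:
    """Two-group DE on the log2 scale: |logFC| > threshold AND p < p_threshold.

    logFC is the difference of group means of the log2(x+1) values
    (in − out).  ``test`` is ``"wilcoxon"`` (rank-sum; exact enumeration at
    small n) or ``"welch"``; Welch falls back to Wilcoxon with a warning
    when either group has fewer than 2 cells.  p-values are raw unless
    ``adjust=True`` (BH).
    """
    if not m.log_transformed:
        raise ValueError("differential expression requires a log-transformed matrix")
    mask = _split_mask(m, in_cells)
    X_in = m.values[mask]
    X_out = m.values[~mask]
    logfc = X_in.mean(axis=0) - X_out.mean(axis=0)

    if test == "welch" and (X_in.shape[0] < 2 or X_out.shape[0] < 2):
        warnings.warn("group size < 2; falling back from Welch to Wilcoxon")
        test = "wilcoxon"
    if test == "welch":
        pvals = sps.ttest_ind(X_in, X_out, equal_var=False, axis=0).pvalue
    elif test == "wilcoxon":
        n_total = m.n_cells
        if n_total <= 12:
            pvals = np.array(
                [rank_sum_test(X_in[:, j], X_out[:, j])[1] for j in range(m.n_molecules)]
            )
        else:
            pvals = rank_sum_test_matrix(X_in, X_out)
    else:
        raise ValueError(f"unknown test {test!r}")
    pvals = np.asarray(pvals, dtype=float)
    p_used = multipletests(pvals, method="fdr_bh")[1] if adjust else pvals
    de_flag = (np.abs(logfc) > logfc_threshold) & (p_used < p_threshold)
    return pd.DataFrame(
        {
            "molecule_id": m.molecule_ids,
            "kind": m.molecule_kind,
            "logFC": logfc,
            "pvalue": pvals,
            "de_flag": de_flag,
        }
    )


def analyze_cluster(
    m_linear: ExpressionMatrix,
    m_log: ExpressionMatrix,
    in_cells,
    cluster_id,
    dropout_threshold: float = 0.5,
    logfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Full differential table (dropout + expression) for one dropout cluster."""
    if list(m_linear.molecule_ids) != list(m_log.molecule_ids):
        raise ValueError("linear and log matrices must share molecules")
    rates = call_differential_dropout(
        dropout_rate_by_group(m_linear, in_cells), dropout_threshold
    )
    de = call_differential_expression(
        m_log, in_cells, logfc_threshold, p_threshold, test
    )
    out = rates.merge(de, on="molecule_id")
    out.insert(0, "cluster_id", cluster_id)
    flags = []
    for dd, dexp in zip(out["dd_flag"], out["de_flag"]):
        f = []
        if dd:
            f.append(DROPOUT_FLAG)
        if dexp:
            f.append(EXPRESSION_FLAG)
        flags.append(",".join(f))
    out["flags"] = flags
    return out


def pool_differential_molecules(results) -> tuple[list[str], pd.DataFrame]:
    """Deduplicated union of flagged molecules across clusters + count table.

    ``results`` maps cluster id → per-cluster differential table
    (:func:`analyze_cluster` output).  Returns the pooled molecule-id list
    (in first-seen order) and a count table with per-cluster DEG/DDG/
    DELR/DDLR counts plus deduplicated totals.
    """
    if isinstance(results, dict):
        items = list(results.items())
    else:
        items = [(df["cluster_id"].iloc[0] if len(df) else i, df) for i, df in enumerate(results)]
    pooled: dict[str, None] = {}
    union: dict[str, set] = {
        k: set() for k in ("DEG", "DDG", "DELR", "DDLR")
    }
    rows = []
    for cid, df in items:
        counts = {}
        for cat, kind, col in (
            ("DEG", "gene", "de_flag"),
            ("DDG", "gene", "dd_flag"),
            ("DELR", "lncRNA", "de_flag"),
            ("DDLR", "lncRNA", "dd_flag"),
        ):
            sel = df[(df["kind"] == kind) & df[col]]
            counts[cat] = len(sel)
            union[cat].update(sel["molecule_id"])
        any_flag = df[df["dd_flag"] | df["de_flag"]]
        for mol in any_flag["molecule_id"]:
            pooled.setdefault(mol)
        counts["cluster_id"] = cid
        counts["n_differential"] = len(any_flag)
        rows.append(counts)
    table = pd.DataFrame(rows, columns=["cluster_id", "DEG", "DDG", "DELR", "DDLR", "n_differential"])
    total = {
        "cluster_id": "Sum",
        "DEG": len(union["DEG"]),
        "DDG": len(union["DDG"]),
        "DELR": len(union["DELR"]),
        "DDLR": len(union["DDLR"]),
        "n_differential": len(pooled),
    }
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    return list(pooled), table
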