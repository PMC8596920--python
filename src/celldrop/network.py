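"""Differential co-expression network and Markov-clustering modules.

All unordered pairs of differential molecules are tested for Spearman
correlation over cells (log2 values; rank correlation is invariant to the
monotone log anyway).  An edge is kept when |rho| strictly exceeds the SCC
threshold (default 0.4) and the two-sided p-value (t approximation) is
below 0.05; edge weight is |rho| with the signed rho retained.  Molecules
with no surviving edge are excluded from the node set.

Modules are read off with Markov clustering (MCL): add self-loops (weight
= the node's maximum incident edge weight), column-normalize, then iterate
expansion (matrix power), inflation (entrywise power followed by
re-normalization) and pruning until the matrix is stable.  Each node is
assigned to the attractor row holding most of its column mass, which makes
the modules an exact partition of the node set; modules are numbered by
decreasing size.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ExpressionMatrix

__all__ = [
    "spearman_with_p",
    "build_network",
    "network_stats",
    "mcl_cluster",
    "module_features",
    "ModuleFeatureMatrix",
]


def _spearman_p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via t = rho sqrt((n−2)/(1−rho²)); |rho| = 1 → p = 0."""
    rho = np.asarray(rho, dtype=float)
    p = np.zeros_like(rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    interior = np.abs(rho) < 1.0
    p[interior] = 2.0 * sps.t.sf(np.abs(t[interior]), n - 2)
    p[np.isnan(rho)] = np.nan
    return p


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho (mid-ranks) and two-sided t-approximation p-value.

    Returns (nan, nan) when either vector is constant (rank variance 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) > 1.0 - 1e-12:  # exact rank (anti-)agreement, fp noise only
        rho = 1.0 if rho > 0 else -1.0
    return rho, float(_spearman_p_from_rho(np.array(rho), n))


def _spearman_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and p over columns of a cells × molecules block."""
    n_cells, n_mol = values.shape
    ranks = sps.rankdata(values, axis=0)
    sd = ranks.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    snap = np.abs(rho) > 1.0 - 1e-12
    rho[snap] = np.sign(rho[snap])
    const = sd == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p = _spearman_p_from_rho(rho, n_cells)
    return rho, p


def build_network(
    m: ExpressionMatrix,
    scc_threshold: float = 0.4,
    p_threshold: float = 0.05,
    molecule_ids=None,
) -> nx.Graph:
    """Weighted differential co-expression network.

    ``molecule_ids`` restricts the matrix to the differential molecules
    (defaults to all columns).  Nodes are molecules with at least one
    retained edge; edges carry ``rho`` (signed), ``weight`` = |rho| and
    ``pvalue``.  Constant molecules are skipped with a warning.
    """
    if molecule_ids is not None:
        m = m.subset_molecules(list(molecule_ids))
    if m.n_molecules < 2:
        raise ValueError("need >= 2 molecules to build a network")
    rho, p = _spearman_matrix(m.values)
    n_const = int(np.isnan(np.diag(rho)).sum())
    if n_const:
        warnings.warn(f"{n_const} constant molecules skipped in network construction")
    g = nx.Graph()
    iu, ju = np.triu_indices(m.n_molecules, k=1)
    with np.errstate(invalid="ignore"):
        keep = (np.abs(rho[iu, ju]) > scc_threshold) & (p[iu, ju] < p_threshold)
    keep &= ~np.isnan(rho[iu, ju])
    if not keep.any():
        warnings.warn("empty co-expression network: no pair passed the thresholds")
    for i, j in zip(iu[keep], ju[keep]):
        u, v = m.molecule_ids[i], m.molecule_ids[j]
        g.add_node(u, kind=str(m.molecule_kind[i]))
        g.add_node(v, kind=str(m.molecule_kind[j]))
        g.add_edge(
            u, v,
            rho=float(rho[i, j]),
            weight=float(abs(rho[i, j])),
            pvalue=float(p[i, j]),
        )
    return g


def network_stats(net: nx.Graph) -> dict:
    """Descriptive summary: degrees, edge signs, hubs, log-log degree slope."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = dict(net.degree())
    rhos = [d["rho"] for _, _, d in net.edges(data=True)]
    n_pos = int(sum(r > 0 for r in rhos))
    n_neg = int(sum(r < 0 for r in rhos))
    hubs = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
    degree_vals = np.array(sorted(degrees.values(), reverse=True))
    slope = None
    uniq, counts = np.unique(degree_vals[degree_vals > 0], return_counts=True)
    if len(uniq) >= 2:
        slope = float(np.polyfit(np.log(uniq), np.log(counts), 1)[0])
    max_abs_rho = float(max(abs(r) for r in rhos)) if rhos else 0.0
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "max_abs_rho": max_abs_rho,
        "degrees": degrees,
        "hubs": hubs,
        "degree_loglog_slope": slope,
    }


def mcl_cluster(
    net: nx.Graph,
    inflation: float = 2.5,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[set[str]]:
    """Markov clustering of the weighted network into differential modules.

    Returns a list of member-id sets partitioning the node set, ordered by
    decreasing size (ties by smallest node position in the graph's
    insertion order).  Disconnected components are never merged.
    """
    nodes = list(net.nodes)
    if not nodes:
        raise ValueError("empty network")
    n = len(nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, d in net.edges(data=True):
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = d["weight"]
    # self-loops: max incident weight (1 for isolated nodes)
    loop = A.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(A, loop)
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        M_new = np.linalg.matrix_power(M, expansion)
        M_new = M_new**inflation
        M_new[M_new < prune] = 0.0
        colsum = M_new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M_new = M_new / colsum
        if np.abs(M_new - M).max() < tol:
            M = M_new
            converged = True
            break
        M = M_new
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")
    # each node goes to the attractor row holding most of its column mass
    owner = M.argmax(axis=0)
    modules: dict[int, set[str]] = {}
    for j, i in enumerate(owner):
        modules.setdefault(int(i), set()).add(nodes[j])
    ordered = sorted(
        modules.values(), key=lambda s: (-len(s), min(pos[u] for u in s))
    )
    return ordered


class ModuleFeatureMatrix:
    """Cells × modules matrix of average member expression (log2 scale)."""

    def __init__(self, values: np.ndarray, cell_ids: list[str], module_ids: list[int]):
        self.values = np.asarray(values, dtype=float)
        self.cell_ids = list(cell_ids)
        self.module_ids = list(module_ids)
        if self.values.shape != (len(self.cell_ids), len(self.module_ids)):
            raise ValueError("shape mismatch in module feature matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=self.cell_ids,
            columns=[f"module_{m}" for m in self.module_ids],
        )


def module_features(m: ExpressionMatrix, modules: list[set[str]]) -> ModuleFeatureMatrix:
    """Per cell, the unweighted mean log2 expression of each module's members."""
    if not m.log_transformed:
        raise ValueError("module features are defined on the log2 matrix")
    feats = np.zeros((m.n_cells, len(modules)))
    for k, members in enumerate(modules):
        if not members:
            raise ValueError(f"module {k + 1} is empty")
        idx = m.molecule_index(sorted(members))
        feats[:, k] = m.values[:, idx].mean(axis=1)
    return ModuleFeatureMatrix(feats, list(m.cell_ids), list(range(1, len(modules) + 1)))
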