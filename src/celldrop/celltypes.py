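"""Cell typing on module features and candidate cell-marker calling.

Cells are clustered a second time — Manhattan distance on the module
features, z-scored, DBSCAN with the silhouette-maximizing parameter search
— and the clusters become cell types lettered A, B, C, … by decreasing
size.  DBSCAN noise cells are collected into the pseudo-type "0", which is
kept in every "remaining cells" comparison group but never itself tested
for markers (a flag enables testing it as a validity check).

Candidate cell markers for a type are molecules with |log2 fold change|
strictly above 2 versus all remaining cells and p < 0.05 from a two-group
linear-model t-test with optional empirical-Bayes variance moderation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cluster import (
    ClusterAssignment,
    DBSCANParams,
    dbscan,
    manhattan_distance,
    select_dbscan_params,
    zscore_distances,
)
from .matrix import ExpressionMatrix
from .network import ModuleFeatureMatrix, spearman_with_p
from .stats import moderated_ttest

__all__ = [
    "CellTypeAssignment",
    "assign_cell_types",
    "call_markers",
    "within_type_similarity",
    "overlap_with_known",
]

NOISE_TYPE = "0"


def _letter(i: int) -> str:
    """0 → A, 25 → Z, 26 → AA, 27 → AB, …"""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


@dataclass
class CellTypeAssignment:
    """Per-cell type labels: letters by decreasing cluster size, "0" = noise."""

    labels: list[str]
    cell_ids: list[str]
    params: DBSCANParams | None = None

    @property
    def type_names(self) -> list[str]:
        seen = [t for t in dict.fromkeys(self.labels) if t != NOISE_TYPE]
        return sorted(seen, key=lambda t: (len(t), t))

    def members(self, type_name: str) -> list[str]:
        return [c for c, t in zip(self.cell_ids, self.labels) if t == type_name]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.labels:
            out[t] = out.get(t, 0) + 1
        return out


def cluster_to_types(assign: ClusterAssignment) -> CellTypeAssignment:
    """Map numeric DBSCAN labels (1..k by size, −1 noise) to letters / "0"."""
    labels = [NOISE_TYPE if l == -1 else _letter(l - 1) for l in assign.labels]
    return CellTypeAssignment(labels, list(assign.cell_ids), assign.params)


def assign_cell_types(features: ModuleFeatureMatrix, **search_kwargs) -> CellTypeAssignment:
    """Second DBSCAN round on module features → lettered cell types.

    Raises the parameter-search error if no clustering structure exists
    (all-identical feature rows give degenerate distances).
    """
    if features.values.shape[0] < 4:
        raise ValueError("need >= 4 cells")
    if features.values.shape[1] < 1:
        raise ValueError("need >= 1 module feature")
    d = manhattan_distance(features.values, features.cell_ids, source="module_features")
    dz = zscore_distances(d)
    params = select_dbscan_params(dz, **search_kwargs)
    assign = dbscan(dz, params.eps, params.min_pts)
    assign.params = params
    return cluster_to_types(assign)


def call_markers(
    m: ExpressionMatrix,
    types: CellTypeAssignment,
    logfc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    moderated: bool = True,
    test_noise_type: bool = False,
) -> pd.DataFrame:
    """Candidate cell markers per type: |logFC| > 2 (strict) and p < 0.05.

    Each lettered type is compared with all remaining cells (type "0"
    included in the remainder).  Types with fewer than 2 cells are skipped
    with a warning.  Returns rows
    ``cell_type, molecule_id, kind, logFC, pvalue, direction``.
    """
    if not m.log_transformed:
        raise ValueError("marker calling requires the log2 matrix")
    if list(types.cell_ids) != list(m.cell_ids):
        raise ValueError("cell ids of matrix and type assignment differ")
    labels = np.array(types.labels, dtype=object)
    rows = []
    to_test = list(types.type_names)
    if test_noise_type and NOISE_TYPE in labels:
        to_test.append(NOISE_TYPE)
    for t in to_test:
        mask = labels == t
        if mask.sum() < 2:
            warnings.warn(f"cell type {t} has < 2 cells; skipped in marker calling")
            continue
        if (~mask).sum() < 2:
            warnings.warn(f"cell type {t} leaves < 2 remaining cells; skipped")
            continue
        logfc, pvals = moderated_ttest(m.values[mask], m.values[~mask], moderated=moderated)
        keep = (np.abs(logfc) > logfc_threshold) & (pvals < p_threshold)
        for j in np.flatnonzero(keep):
            rows.append(
                {
                    "cell_type": t,
                    "molecule_id": m.molecule_ids[j],
                    "kind": str(m.molecule_kind[j]),
                    "logFC": float(logfc[j]),
                    "pvalue": float(pvals[j]),
                    "direction": "up" if logfc[j] > 0 else "down",
                }
            )
    return pd.DataFrame(
        rows, columns=["cell_type", "molecule_id", "kind", "logFC", "pvalue", "direction"]
    )


def within_type_similarity(
    m: ExpressionMatrix, types: CellTypeAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho for every within-type cell pair, plus per-type summary.

    Type "0" is included for contrast.  Returns (pairs, summary): pairs has
    ``cell_type, cell_a, cell_b, rho``; summary has per-type n_pairs and
    min/mean/max rho.
    """
    labels = np.array(types.labels, dtype=object)
    pair_rows = []
    for t in dict.fromkeys(types.labels):
        idx = np.flatnonzero(labels == t)
        for i, j in combinations(idx, 2):
            rho, _ = spearman_with_p(m.values[i], m.values[j])
            pair_rows.append(
                {
                    "cell_type": t,
                    "cell_a": m.cell_ids[i],
                    "cell_b": m.cell_ids[j],
                    "rho": rho,
                }
            )
    pairs = pd.DataFrame(pair_rows, columns=["cell_type", "cell_a", "cell_b", "rho"])
    if len(pairs):
        summary = (
            pairs.groupby("cell_type")["rho"]
            .agg(n_pairs="count", min="min", mean="mean", max="max")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["cell_type", "n_pairs", "min", "mean", "max"])
    return pairs, summary


def overlap_with_known(markers: pd.DataFrame, known) -> pd.DataFrame:
    """Per-type overlap of called markers with a user-supplied molecule list.

    Exact string matching on molecule_id.  Returns per cell type the marker
    count, the overlap count and the overlap percentage (0 when the type
    has no markers).
    """
    known = set(map(str, known))
    if not known:
        raise ValueError("known molecule list is empty")
    rows = []
    for t, grp in markers.groupby("cell_type", sort=True):
        ids = set(grp["molecule_id"])
        n_known = len(ids & known)
        rows.append(
            {
                "cell_type": t,
                "n_markers": len(ids),
                "n_known": n_known,
                "percentage": 100.0 * n_known / len(ids) if ids else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["cell_type", "n_markers", "n_known", "percentage"])
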