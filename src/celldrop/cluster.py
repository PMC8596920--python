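"""Density-based clustering of cells on dropout or module features.

Cells are compared by Manhattan distance (robust with many exact zeros),
the distance is z-score normalized ("dropout distance"), and DBSCAN is run
on the precomputed distances.  The two DBSCAN hyperparameters are chosen
by a silhouette-maximizing coordinate ascent:

  Step 1 — with MinPts fixed, compute every cell's distance to its
           MinPts-th nearest neighbour; sweep eps over the [min, max]
           range of these k-distances with a fixed step and keep the eps
           maximizing the silhouette coefficient.
  Step 2 — with eps fixed, sweep MinPts over [2, ceil(0.1 n)] and keep
           the maximizer.
  Step 3 — repeat until (eps, MinPts) is stable.

The same machinery serves both the dropout-cluster stage (binary dropout
features) and the final cell-typing stage (module features).

All tie-breaks are deterministic: smaller eps, then smaller MinPts; border
points reachable from several clusters go to the cluster of their
lowest-index core neighbour; clusters are renumbered 1..k by decreasing
size (ties by smallest member index), noise is −1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .matrix import ExpressionMatrix

__all__ = [
    "DropoutFeatureMatrix",
    "DistanceMatrix",
    "DBSCANParams",
    "ClusterAssignment",
    "binarize",
    "manhattan_distance",
    "zscore_distances",
    "dbscan",
    "silhouette",
    "select_dbscan_params",
    "NoClusterStructureError",
]

NOISE = -1


class NoClusterStructureError(RuntimeError):
    """Raised when no (eps, MinPts) pair produces at least two clusters."""


@dataclass
class DropoutFeatureMatrix:
    """Binary cells × molecules matrix: 1 = expressed, 0 = dropout."""

    values: np.ndarray
    cell_ids: list[str]
    molecule_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("dropout feature matrix must be binary")


@dataclass
class DistanceMatrix:
    """Symmetric cells × cells distances, optionally z-score normalized."""

    values: np.ndarray
    cell_ids: list[str]
    zscored: bool = False
    source: str = "dropout_features"
    # affine parameters recorded by zscore_distances so that scale-dependent
    # scores (silhouette) can be evaluated on the original metric
    zscore_mu: float | None = None
    zscore_sigma: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n_cells, k=1)
        return self.values[iu]


@dataclass
class DBSCANParams:
    eps: float
    min_pts: int
    silhouette: float
    n_clusters: int
    n_noise: int


@dataclass
class ClusterAssignment:
    """Per-cell integer labels: −1 noise, clusters 1..k by decreasing size."""

    labels: np.ndarray
    cell_ids: list[str]
    params: DBSCANParams | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    @property
    def n_noise(self) -> int:
        return int((self.labels == NOISE).sum())

    def members(self, label: int) -> list[str]:
        return [c for c, l in zip(self.cell_ids, self.labels) if l == label]


def binarize(m: ExpressionMatrix) -> DropoutFeatureMatrix:
    """1 where expression > 0, else 0 (idempotent; zeros survive any log)."""
    return DropoutFeatureMatrix(
        (m.values > 0).astype(np.uint8), list(m.cell_ids), list(m.molecule_ids)
    )


def manhattan_distance(features, cell_ids=None, source: str = "dropout_features") -> DistanceMatrix:
    """Pairwise Manhattan (cityblock) distance between cell feature rows."""
    if isinstance(features, DropoutFeatureMatrix):
        cell_ids = features.cell_ids
        X = features.values.astype(float)
        source = "dropout_features"
    else:
        X = np.asarray(features, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(X.shape[0])]
    d = squareform(pdist(X, metric="cityblock"))
    return DistanceMatrix(d, list(cell_ids), zscored=False, source=source)


def zscore_distances(d: DistanceMatrix) -> DistanceMatrix:
    """z-score every entry using the off-diagonal mean and sample sd.

    The transform is monotone affine, so distance orderings (and hence
    DBSCAN structure, up to the eps scale) are preserved.
    """
    if d.n_cells < 2:
        raise ValueError("need >= 2 cells")
    off = d.offdiag()
    mu = off.mean()
    sd = off.std(ddof=1) if off.size > 1 else 0.0
    if sd == 0:
        raise ValueError("degenerate distances: all pairwise distances equal")
    return DistanceMatrix(
        (d.values - mu) / sd, list(d.cell_ids), zscored=True, source=d.source,
        zscore_mu=float(mu), zscore_sigma=float(sd),
    )


def dbscan(d: DistanceMatrix, eps: float, min_pts: int) -> ClusterAssignment:
    """DBSCAN on a precomputed distance matrix.

    A point is core iff at least ``min_pts`` points (itself included) lie
    within distance eps.  Clusters are connected components of core points
    plus reachable border points; unreachable points are noise (−1).
    """
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    D = d.values
    n = d.n_cells
    within = D <= eps
    neighbour_counts = within.sum(axis=1)
    core = neighbour_counts >= min_pts
    labels = np.full(n, NOISE, dtype=int)
    if core.any():
        core_idx = np.flatnonzero(core)
        sub = within[np.ix_(core_idx, core_idx)]
        n_comp, comp = connected_components(csr_matrix(sub), directed=False)
        labels[core_idx] = comp
        # border points: first (lowest-index) core neighbour decides
        non_core = np.flatnonzero(~core)
        if non_core.size:
            reach = within[np.ix_(non_core, core_idx)]
            has_core = reach.any(axis=1)
            first_core = reach.argmax(axis=1)
            for i, ok, j in zip(non_core, has_core, first_core):
                if ok:
                    labels[i] = comp[j]
    labels = _renumber_by_size(labels)
    return ClusterAssignment(labels, list(d.cell_ids))


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size; ties by smallest member index."""
    out = np.full_like(labels, NOISE)
    uniq = [l for l in np.unique(labels) if l != NOISE]
    sizes = [((labels == l).sum(), -int(np.flatnonzero(labels == l)[0]), l) for l in uniq]
    sizes.sort(reverse=True)
    for new, (_, _, old) in enumerate(sizes, start=1):
        out[labels == old] = new
    return out


def silhouette(d: DistanceMatrix, labels) -> float:
    """Mean silhouette over non-noise points; −1 sentinel if < 2 clusters.

    s(i) = (b − a) / max(a, b) with a the mean distance to the point's own
    cluster (excluding itself) and b the smallest mean distance to another
    cluster; points in singleton clusters contribute 0.

    For a z-scored matrix carrying its affine parameters the score is
    computed on the de-normalized (original-scale) distances — the
    labelling is unaffected by the monotone affine transform, but the
    silhouette itself is only meaningful on a non-negative metric.
    """
    if isinstance(labels, ClusterAssignment):
        labels = labels.labels
    labels = np.asarray(labels, dtype=int)
    D = d.values
    if d.zscored and d.zscore_mu is not None:
        D = D * d.zscore_sigma + d.zscore_mu
    mask = labels != NOISE
    uniq = np.unique(labels[mask])
    if uniq.size < 2:
        return -1.0
    idx = np.flatnonzero(mask)
    sub = D[np.ix_(idx, idx)]
    sub_labels = labels[idx]
    k = uniq.size
    # mean distance from each point to each cluster
    ind = np.zeros((idx.size, k))
    for c, lab in enumerate(uniq):
        ind[sub_labels == lab, c] = 1.0
    sizes = ind.sum(axis=0)
    sums = sub @ ind  # (n_pts, k)
    s_vals = np.zeros(idx.size)
    for i in range(idx.size):
        c = int(np.flatnonzero(uniq == sub_labels[i])[0])
        if sizes[c] == 1:
            s_vals[i] = 0.0
            continue
        a = sums[i, c] / (sizes[c] - 1)
        others = [sums[i, j] / sizes[j] for j in range(k) if j != c]
        b = min(others)
        denom = max(a, b)
        s_vals[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s_vals.mean())


def _k_distances(D: np.ndarray, min_pts: int) -> np.ndarray:
    """Distance of each point to its MinPts-th closest point, itself included.

    This is the smallest eps at which the point becomes core (the core
    condition counts the point itself), i.e. the (MinPts−1)-th nearest
    neighbour distance.
    """
    n = D.shape[0]
    k = min(max(min_pts - 1, 1), n - 1)
    order = np.sort(D + np.diag(np.full(n, np.inf)), axis=1)
    return order[:, k - 1]


def select_dbscan_params(
    d: DistanceMatrix,
    init_min_pts: int = 4,
    eps_step: float = 0.001,
    max_rounds: int = 20,
    min_valid_frac: float = 0.5,
    max_grid: int = 200_000,
) -> DBSCANParams:
    """Silhouette-maximizing coordinate ascent over (eps, MinPts).

    A labelling only scores when it has >= 2 clusters and at least
    ``min_valid_frac`` of the points non-noise (otherwise −1), so the
    search cannot win by declaring almost everything noise.  Returns the
    best pair examined anywhere during the sweeps; raises
    :class:`NoClusterStructureError` when nothing ever yields 2 clusters.
    """
    n = d.n_cells
    if n < 4:
        raise ValueError("need >= 4 cells for the parameter search")
    D = d.values
    uniq_dists = np.unique(d.offdiag())
    min_pts_hi = max(2, math.ceil(0.1 * n))
    cache: dict[tuple[int, int], tuple[float, ClusterAssignment]] = {}

    def score_at(eps: float, min_pts: int) -> tuple[float, ClusterAssignment]:
        # labellings change only when eps crosses a pairwise distance
        key = (min_pts, int(np.searchsorted(uniq_dists, eps, side="right")))
        if key not in cache:
            assign = dbscan(d, eps, min_pts)
            non_noise = n - assign.n_noise
            if assign.n_clusters < 2 or non_noise < min_valid_frac * n:
                sil = -1.0
            else:
                sil = silhouette(d, assign.labels)
            cache[key] = (sil, assign)
        return cache[key]

    best: tuple[float, float, int] | None = None  # (sil, eps, min_pts)

    def consider(sil: float, eps: float, min_pts: int) -> None:
        nonlocal best
        if sil <= -1.0:
            return
        if (
            best is None
            or sil > best[0]
            or (sil == best[0] and (eps, min_pts) < (best[1], best[2]))
        ):
            best = (sil, eps, min_pts)

    min_pts = int(init_min_pts)
    eps = None
    for _ in range(max_rounds):
        prev = (eps, min_pts)
        # Step 1: eps sweep over the MinPts-distance range
        kd = _k_distances(D, min_pts)
        lo, hi = float(kd.min()), float(kd.max())
        n_steps = int(np.floor((hi - lo) / eps_step)) + 1
        if n_steps > max_grid:  # guard only; never reached at sane scales
            n_steps = max_grid
        grid = lo + eps_step * np.arange(n_steps)
        if grid[-1] < hi:
            grid = np.append(grid, hi)
        best_step1 = None
        for e in grid:
            sil, _ = score_at(float(e), min_pts)
            consider(sil, float(e), min_pts)
            if best_step1 is None or sil > best_step1[0]:
                best_step1 = (sil, float(e))
        eps = best_step1[1]
        # Step 2: MinPts sweep at fixed eps
        best_step2 = None
        for mp in range(2, min_pts_hi + 1):
            sil, _ = score_at(eps, mp)
            consider(sil, eps, mp)
            if best_step2 is None or sil > best_step2[0]:
                best_step2 = (sil, mp)
        min_pts = best_step2[1]
        if (eps, min_pts) == prev:
            break
    if best is None:
        raise NoClusterStructureError(
            "no cluster structure found: no (eps, MinPts) yields >= 2 clusters"
        )
    sil, eps, min_pts = best
    _, assign = score_at(eps, min_pts)
    return DBSCANParams(
        eps=eps,
        min_pts=min_pts,
        silhouette=sil,
        n_clusters=assign.n_clusters,
        n_noise=assign.n_noise,
    )
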