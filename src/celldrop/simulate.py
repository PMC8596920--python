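"""Seeded synthetic scRNA-seq data with the structure the pipeline assumes.

The generator plants, in a cells × molecules matrix:

* ``n_types`` cell types with distinct mean-expression profiles;
* per-type marker molecules whose mean is multiplied by a stated fold
  change in their own type;
* co-expression modules whose members share a latent per-cell factor
  inducing a chosen within-module rank correlation;
* per-type dropout shifts (molecules whose dropout probability is moved
  by a stated signed delta in one type; the default −0.6 switches the
  molecule ON in its type) — the planted "differential dropout" signal;
* Michaelis–Menten zero inflation: every entry is zeroed independently
  with probability p = 1 − S/(K + S) evaluated at the molecule's
  type-specific mean S (plus any planted shift, clipped to [0, 1]).

The configured means are expected OBSERVED means: non-zero values are
drawn around mean/(1 − p) with mean-one log-normal noise, so the empirical
mean of a molecule matches its configured mean and unperturbed molecules
sit exactly on the Michaelis–Menten curve in observed (S, P) space — the
property the dropout-based feature selection tests.

Optional outlier cells are doublet-like: each mixes the mean profiles of a
distinct pair of types, so it sits between clusters — planted DBSCAN noise.
A ``k_outlier_spec`` plants molecules whose dropout obeys an inflated
Michaelis constant (elevated dropout for their expression level), the
ground truth for feature-selection power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .matrix import GENE, LNCRNA, ExpressionMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "evaluate"]


@dataclass
class SimulationConfig:
    """Generator settings; the defaults define the standard study conditions.

    300 cells in 4 balanced types over 1,000 genes + 200 lncRNAs, global
    Michaelis constant K = 10, 40 sixteen-fold markers and 40 molecules
    switched on in their own type (dropout shift −0.6), two correlated 30-molecule
    modules, log-normal base means (meanlog 1, sdlog 1; lncRNAs scaled to
    half the gene level to mirror their sparser detection) and log-normal
    multiplicative expression noise with sd 0.5.
    """

    n_cells: int = 300
    n_genes: int = 1000
    n_lncrnas: int = 200
    n_types: int = 4
    type_proportions: list[float] | None = None
    global_K: float = 10.0
    marker_spec: list[tuple[int, float]] | None = None     # per type: (n, fold)
    module_spec: list[tuple[int, float]] = field(default_factory=lambda: [(30, 0.7), (30, 0.7)])
    # per type: (n, delta); delta < 0 lowers dropout in the type (the
    # molecule switches ON there), delta > 0 raises it
    dropout_shift_spec: list[tuple[int, float]] | None = None
    k_outlier_spec: tuple[int, float] | None = None  # (n, K multiplier)
    base_meanlog: float = 1.0
    base_sdlog: float = 1.0
    lncrna_mean_scale: float = 0.5
    noise_sd: float = 0.5
    n_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_spec is None:
            self.marker_spec = [(40, 16.0)] * self.n_types
        if self.dropout_shift_spec is None:
            self.dropout_shift_spec = [(40, -0.6)] * self.n_types
        if self.type_proportions is None:
            self.type_proportions = [1.0 / self.n_types] * self.n_types
        self.validate()

    @property
    def n_molecules(self) -> int:
        return self.n_genes + self.n_lncrnas

    def validate(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_types) < 1 or self.n_lncrnas < 0:
            raise ValueError("counts must be positive")
        if self.n_outliers < 0 or self.n_outliers >= self.n_cells:
            raise ValueError("n_outliers must be in [0, n_cells)")
        if len(self.type_proportions) != self.n_types:
            raise ValueError("type_proportions length must equal n_types")
        if abs(sum(self.type_proportions) - 1.0) > 1e-8:
            raise ValueError("type_proportions must sum to 1")
        if len(self.marker_spec) != self.n_types or len(self.dropout_shift_spec) != self.n_types:
            raise ValueError("marker_spec and dropout_shift_spec need one entry per type")
        if any(f <= 0 for _, f in self.marker_spec):
            raise ValueError("fold_change must be > 0")
        if any(not (0 < r < 1) for _, r in self.module_spec):
            raise ValueError("within_rho must be in (0, 1)")
        if self.global_K <= 0:
            raise ValueError("global_K must be > 0")
        n_special = (
            sum(n for n, _ in self.marker_spec)
            + sum(n for n, _ in self.dropout_shift_spec)
            + sum(n for n, _ in self.module_spec)
            + (self.k_outlier_spec[0] if self.k_outlier_spec else 0)
        )
        if n_special > self.n_molecules:
            raise ValueError(
                f"planted molecules ({n_special}) exceed molecule count ({self.n_molecules})"
            )


@dataclass
class GroundTruth:
    """Planted structure: 1..k type labels (0 = outlier), marker/module/shift sets."""

    cell_ids: list[str]
    cell_type_labels: np.ndarray  # int; 0 marks planted outliers
    marker_ids: dict[int, list[str]]
    k_outlier_ids: list[str]
    module_memberships: dict[int, list[str]]
    dropout_shifted: dict[int, list[str]]


def _type_sizes(n: int, proportions: list[float]) -> list[int]:
    raw = [p * n for p in proportions]
    sizes = [int(np.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one seeded dataset; byte-identical across runs with the same config."""
    rng = np.random.default_rng(config.seed)
    n_mol = config.n_molecules
    mol_ids = [f"G{i:05d}" for i in range(config.n_genes)] + [
        f"L{i:05d}" for i in range(config.n_lncrnas)
    ]
    kinds = np.array([GENE] * config.n_genes + [LNCRNA] * config.n_lncrnas, dtype=object)

    base = rng.lognormal(config.base_meanlog, config.base_sdlog, size=n_mol)
    base[config.n_genes:] *= config.lncrna_mean_scale

    # disjoint special molecule sets, planted only where the signal is
    # realizable: markers need at least median base expression (a fold
    # change on a molecule that is undetectable everywhere carries no
    # signal), and a dropout shift of delta needs base dropout leaving
    # room for the full |delta| to appear
    pool = list(rng.permutation(n_mol))
    expressed = base >= np.median(base)
    p_base = 1.0 - base / (config.global_K + base)

    def take(k: int, eligible: np.ndarray | None = None) -> np.ndarray:
        out = []
        rest = []
        while pool and len(out) < k:
            j = pool.pop(0)
            if eligible is not None and not eligible[j]:
                rest.append(j)
            else:
                out.append(j)
        pool.extend(rest)
        if len(out) < k:
            raise ValueError("not enough molecules left for the planted sets")
        return np.sort(np.array(out, dtype=int))

    marker_idx = {
        t + 1: take(n, eligible=expressed)
        for t, (n, _) in enumerate(config.marker_spec)
    }
    shift_idx = {}
    for t, (n, delta) in enumerate(config.dropout_shift_spec):
        if delta >= 0:
            ok = p_base <= 1.0 - delta - 0.05
        else:
            ok = p_base >= -delta + 0.05
        shift_idx[t + 1] = take(n, eligible=ok)
    module_idx = {m + 1: take(sz) for m, (sz, _) in enumerate(config.module_spec)}
    k_out_idx = take(config.k_outlier_spec[0]) if config.k_outlier_spec else np.array([], dtype=int)

    # type-specific means and dropout shifts
    type_means = np.tile(base, (config.n_types, 1))
    shifts = np.zeros((config.n_types, n_mol))
    for t in range(1, config.n_types + 1):
        _, fold = config.marker_spec[t - 1]
        type_means[t - 1, marker_idx[t]] *= fold
        _, delta = config.dropout_shift_spec[t - 1]
        shifts[t - 1, shift_idx[t]] = delta

    # cell assignment (planted outliers labelled 0), order shuffled
    n_regular = config.n_cells - config.n_outliers
    sizes = _type_sizes(n_regular, config.type_proportions)
    labels = np.concatenate(
        [np.full(s, t + 1) for t, s in enumerate(sizes)] + [np.zeros(config.n_outliers)]
    ).astype(int)
    labels = labels[rng.permutation(config.n_cells)]
    cell_ids = [f"cell{i:04d}" for i in range(config.n_cells)]

    K = config.global_K
    mean_mat = np.empty((config.n_cells, n_mol))
    shift_mat = np.zeros((config.n_cells, n_mol))
    # doublet-like outliers: each mixes the profiles of a distinct pair of
    # types (weights near 1/2), so outliers sit between clusters, far from
    # every type and from each other in any type-signature feature space
    from itertools import combinations as _combinations

    type_pairs = list(_combinations(range(config.n_types), 2)) or [(0, 0)]
    pair_order = rng.permutation(len(type_pairs))
    for i, lab in enumerate(labels):
        if lab == 0:
            o = int(np.flatnonzero(np.flatnonzero(labels == 0) == i)[0])
            a, b = type_pairs[pair_order[o % len(type_pairs)]]
            w = rng.uniform(0.4, 0.6)
            mean_mat[i] = w * type_means[a] + (1.0 - w) * type_means[b]
        else:
            mean_mat[i] = type_means[lab - 1]
            shift_mat[i] = shifts[lab - 1]
    p_drop = np.clip(1.0 - mean_mat / (K + mean_mat) + shift_mat, 0.0, 1.0)
    if len(k_out_idx):
        # molecules obeying an inflated Michaelis constant: elevated
        # dropout for their expression level, the planted feature-selection
        # signal (their observed K_j sits at K x multiplier)
        K_hi = K * config.k_outlier_spec[1]
        sub = mean_mat[:, k_out_idx]
        p_drop[:, k_out_idx] = np.clip(
            1.0 - sub / (K_hi + sub) + shift_mat[:, k_out_idx], 0.0, 1.0
        )

    # correlated log-normal noise with unit mean
    z = rng.standard_normal((config.n_cells, n_mol))
    for m, (sz, rho) in enumerate(config.module_spec, start=1):
        f = rng.standard_normal(config.n_cells)
        idx = module_idx[m]
        z[:, idx] = np.sqrt(rho) * f[:, None] + np.sqrt(1.0 - rho) * z[:, idx]
    noise = np.exp(config.noise_sd * z - 0.5 * config.noise_sd**2)

    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(p_drop < 1.0, mean_mat / (1.0 - p_drop), 0.0)
    values = scale * noise
    keep = rng.random((config.n_cells, n_mol)) >= p_drop
    values = np.where(keep, values, 0.0)

    m = ExpressionMatrix(values, cell_ids, mol_ids, kinds)
    truth = GroundTruth(
        cell_ids=cell_ids,
        cell_type_labels=labels,
        marker_ids={t: [mol_ids[j] for j in idx] for t, idx in marker_idx.items()},
        k_outlier_ids=[mol_ids[j] for j in k_out_idx],
        module_memberships={k: [mol_ids[j] for j in idx] for k, idx in module_idx.items()},
        dropout_shifted={t: [mol_ids[j] for j in idx] for t, idx in shift_idx.items()},
    )
    return m, truth


def write_truth(truth: GroundTruth, outdir) -> None:
    """Write the planted structure as plain TSVs (for the CLI round trip)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"cell_id": truth.cell_ids, "cell_type": truth.cell_type_labels}
    ).to_csv(outdir / "truth_cell_types.tsv", sep="\t", index=False)
    pd.Series(truth.k_outlier_ids, dtype=str).to_csv(
        outdir / "truth_k_outliers.txt", index=False, header=False
    )
    for name, mapping in (
        ("truth_markers.tsv", truth.marker_ids),
        ("truth_modules.tsv", truth.module_memberships),
        ("truth_shifted.tsv", truth.dropout_shifted),
    ):
        pd.DataFrame(
            [{"group": k, "molecule_id": mol} for k, ids in mapping.items() for mol in ids]
        ).to_csv(outdir / name, sep="\t", index=False)


def read_truth(indir) -> GroundTruth:
    from pathlib import Path

    indir = Path(indir)
    cells = pd.read_csv(indir / "truth_cell_types.tsv", sep="\t")

    def _groups(name: str) -> dict[int, list[str]]:
        df = pd.read_csv(indir / name, sep="\t")
        if df.empty:
            return {}
        return {
            int(k): list(grp["molecule_id"].astype(str))
            for k, grp in df.groupby("group")
        }

    kfile = indir / "truth_k_outliers.txt"
    k_ids = [l.strip() for l in kfile.read_text().splitlines() if l.strip()] if kfile.exists() else []
    return GroundTruth(
        cell_ids=list(cells["cell_id"].astype(str)),
        cell_type_labels=cells["cell_type"].to_numpy(dtype=int),
        marker_ids=_groups("truth_markers.tsv"),
        k_outlier_ids=k_ids,
        module_memberships=_groups("truth_modules.tsv"),
        dropout_shifted=_groups("truth_shifted.tsv"),
    )


def _map_types_to_truth(truth: GroundTruth, labels: list[str], cell_ids: list[str]) -> dict[str, int]:
    """Majority-overlap mapping of lettered types to planted type numbers."""
    truth_by_cell = dict(zip(truth.cell_ids, truth.cell_type_labels))
    mapping: dict[str, int] = {}
    for t in sorted(set(labels) - {"0"}):
        planted = [truth_by_cell[c] for c, l in zip(cell_ids, labels) if l == t]
        vals, counts = np.unique(planted, return_counts=True)
        mapping[t] = int(vals[counts.argmax()])
    return mapping


def evaluate(truth: GroundTruth, types, markers: pd.DataFrame | None = None,
             modules: list[set[str]] | None = None) -> dict:
    """Ground-truth metrics: ARI, planted-marker precision/recall, module F1.

    Cells the pipeline labelled "0" (noise) are excluded from the ARI and
    reported separately, together with the fraction of planted outliers
    that ended up in type 0.
    """
    if set(types.cell_ids) != set(truth.cell_ids):
        raise ValueError("cell universes of truth and assignment differ")
    truth_by_cell = dict(zip(truth.cell_ids, truth.cell_type_labels))
    assigned = np.array(types.labels, dtype=object)
    true_vec = np.array([truth_by_cell[c] for c in types.cell_ids])
    non_noise = assigned != "0"
    metrics: dict = {
        "n_cells": len(assigned),
        "n_assigned_noise": int((~non_noise).sum()),
        "n_types_found": len(set(assigned[non_noise])),
    }
    if non_noise.sum() >= 2 and len(set(true_vec[non_noise])) >= 1:
        metrics["ari"] = float(
            adjusted_rand_score(true_vec[non_noise], assigned[non_noise].astype(str))
        )
    else:
        metrics["ari"] = float("nan")
    n_outliers = int((true_vec == 0).sum())
    if n_outliers:
        metrics["outlier_recall"] = float(
            ((true_vec == 0) & ~non_noise).sum() / n_outliers
        )

    if markers is not None:
        # precision counts a call as planted signal when it is either a
        # planted marker of the mapped type or one of that type's dropout-
        # shifted molecules (a genuine planted down-regulation); recall is
        # over the planted fold-change markers only
        mapping = _map_types_to_truth(truth, list(types.labels), list(types.cell_ids))
        tp_prec = 0
        n_called = 0
        per_type = {}
        recovered: dict[int, set] = {}
        for t, planted_t in mapping.items():
            called = set(markers.loc[markers["cell_type"] == t, "molecule_id"])
            planted = set(truth.marker_ids.get(planted_t, []))
            signal = planted | set(truth.dropout_shifted.get(planted_t, []))
            hit_prec = len(called & signal)
            tp_prec += hit_prec
            n_called += len(called)
            recovered.setdefault(planted_t, set()).update(called & planted)
            per_type[t] = {
                "planted_type": planted_t,
                "n_called": len(called),
                "precision": hit_prec / len(called) if called else float("nan"),
                "recall": len(called & planted) / len(planted) if planted else float("nan"),
            }
        n_planted = sum(len(v) for v in truth.marker_ids.values())
        tp_rec = sum(len(v) for v in recovered.values())
        metrics["marker_precision"] = tp_prec / n_called if n_called else float("nan")
        metrics["marker_recall"] = tp_rec / n_planted if n_planted else float("nan")
        metrics["marker_per_type"] = per_type

    if modules is not None:
        f1s = []
        weights = []
        for members in truth.module_memberships.values():
            truth_set = set(members)
            best = 0.0
            for pred in modules:
                inter = len(truth_set & pred)
                if inter == 0:
                    continue
                prec = inter / len(pred)
                rec = inter / len(truth_set)
                best = max(best, 2 * prec * rec / (prec + rec))
            f1s.append(best)
            weights.append(len(truth_set))
        if f1s:
            metrics["module_f1"] = float(np.average(f1s, weights=weights))
    return metrics
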