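"""End-to-end orchestration: preprocess → features → dropout clusters →
differential analysis → co-expression network → MCL modules → cell types →
markers, with every stage's counts recorded in a JSON manifest.

The pipeline itself is fully deterministic; the only randomness in the
package lives in the synthetic-data generator behind a single seed, so two
runs with the same configuration produce byte-identical manifests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .celltypes import assign_cell_types, call_markers, within_type_similarity
from .cluster import (
    NoClusterStructureError,
    binarize,
    dbscan,
    manhattan_distance,
    select_dbscan_params,
    zscore_distances,
)
from .differential import analyze_cluster, pool_differential_molecules
from .features import select_features
from .io import filter_cells_by_detection, filter_molecules, log_transform
from .matrix import ExpressionMatrix
from .network import build_network, mcl_cluster, module_features, network_stats

__all__ = ["RunConfig", "PipelineError", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage thresholds; defaults follow the framework's stated values."""

    # preprocessing
    min_cells: int = 3
    min_mean_norm: float = 1e-5
    cell_fdr: float = 0.05
    # feature selection
    feature_fdr: float = 0.01
    # differential analysis
    dropout_diff: float = 0.5
    de_logfc: float = 1.0
    de_p: float = 0.05
    de_test: str = "wilcoxon"
    # network
    scc: float = 0.4
    scc_p: float = 0.05
    # modules
    mcl_inflation: float = 2.5
    mcl_expansion: int = 2
    mcl_prune: float = 1e-5
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-6
    # markers
    marker_logfc: float = 2.0
    marker_p: float = 0.05
    marker_moderated: bool = True
    # molecule universe for differential/marker tests: the full filtered
    # matrix ("all") or only the dropout-selected features ("selected")
    differential_universe: str = "all"
    marker_universe: str = "all"
    # DBSCAN search
    eps_step: float = 0.001
    init_min_pts: int = 4
    max_rounds: int = 20
    min_valid_frac: float = 0.5
    # misc
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 < self.scc < 1, "scc must be in (0, 1)"),
            (0 < self.scc_p <= 1, "scc_p must be in (0, 1]"),
            (0 < self.de_p <= 1, "de_p must be in (0, 1]"),
            (0 < self.marker_p <= 1, "marker_p must be in (0, 1]"),
            (0 < self.cell_fdr <= 1, "cell_fdr must be in (0, 1]"),
            (0 < self.feature_fdr <= 1, "feature_fdr must be in (0, 1]"),
            (0 <= self.dropout_diff < 1, "dropout_diff must be in [0, 1)"),
            (self.de_logfc >= 0, "de_logfc must be >= 0"),
            (self.marker_logfc >= 0, "marker_logfc must be >= 0"),
            (self.mcl_inflation > 1, "mcl_inflation must be > 1"),
            (self.mcl_expansion >= 2, "mcl_expansion must be >= 2"),
            (self.eps_step > 0, "eps_step must be > 0"),
            (self.init_min_pts >= 2, "init_min_pts must be >= 2"),
            (self.min_cells >= 1, "min_cells must be >= 1"),
            (self.de_test in ("wilcoxon", "welch"), "de_test must be wilcoxon|welch"),
            (self.marker_universe in ("selected", "all"), "marker_universe must be selected|all"),
            (self.differential_universe in ("selected", "all"), "differential_universe must be selected|all"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


def _search_kwargs(config: RunConfig) -> dict:
    return dict(
        init_min_pts=config.init_min_pts,
        eps_step=config.eps_step,
        max_rounds=config.max_rounds,
        min_valid_frac=config.min_valid_frac,
    )


def run_pipeline(
    m: ExpressionMatrix,
    config: RunConfig | None = None,
    outdir=None,
) -> tuple[dict, dict]:
    """Run every stage on a linear-scale expression matrix.

    Returns ``(results, manifest)``: results holds the in-memory objects
    (matrices, assignments, tables, network, modules), manifest the
    JSON-serializable per-stage counts.  When ``outdir`` is given every
    intermediate table and the manifest are written there; on a stage
    failure a partial manifest (with ``failed_stage``) is still written
    and a :class:`PipelineError` raised.
    """
    config = config or RunConfig()
    config.validate()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "celldrop_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    results: dict = {}
    stage = "preprocess"
    try:
        # ---------------- preprocess ----------------
        m_filt = filter_molecules(m, config.min_cells, config.min_mean_norm)
        m_filt, qc = filter_cells_by_detection(m_filt, config.cell_fdr)
        if outdir is not None:
            qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        manifest["stages"]["preprocess"] = {
            "n_cells_in": m.n_cells,
            "n_molecules_in": m.n_molecules,
            "n_molecules_kept": m_filt.n_molecules,
            "n_cells_removed": int(qc["removed"].sum()),
            "n_cells_kept": m_filt.n_cells,
        }
        m_log = log_transform(m_filt)
        results["matrix_linear"] = m_filt
        results["matrix_log"] = m_log

        # ---------------- feature selection ----------------
        stage = "feature_selection"
        feats = select_features(m_filt, config.feature_fdr)
        selected_ids = list(feats.loc[feats["selected"], "molecule_id"])
        if outdir is not None:
            feats.to_csv(outdir / "features.tsv", sep="\t", index=False)
        by_kind = feats[feats["selected"]].groupby("kind").size().to_dict()
        manifest["stages"]["feature_selection"] = {
            "n_selected": len(selected_ids),
            "by_kind": {str(k): int(v) for k, v in by_kind.items()},
            "global_K": {
                str(k): float(v)
                for k, v in feats.groupby("kind")["global_K"].first().items()
            },
        }
        if len(selected_ids) < 2:
            raise NoClusterStructureError(
                "no cluster structure found: fewer than 2 selected features"
            )
        m_sel_linear = m_filt.subset_molecules(selected_ids)
        m_sel_log = m_log.subset_molecules(selected_ids)

        # ---------------- dropout clusters ----------------
        stage = "dropout_clusters"
        try:
            features_bin = binarize(m_sel_linear)
            d = zscore_distances(manhattan_distance(features_bin))
            params = select_dbscan_params(d, **_search_kwargs(config))
            clusters = dbscan(d, params.eps, params.min_pts)
            clusters.params = params
        except ValueError as exc:  # degenerate distances etc.
            raise NoClusterStructureError(f"no cluster structure found: {exc}") from exc
        cluster_sizes = {
            int(l): int((clusters.labels == l).sum())
            for l in sorted(set(clusters.labels))
            if l != -1
        }
        if outdir is not None:
            pd.DataFrame(
                {"cell_id": clusters.cell_ids, "dropout_cluster": clusters.labels}
            ).to_csv(outdir / "dropout_clusters.tsv", sep="\t", index=False)
            (outdir / "dropout_params.json").write_text(
                json.dumps(asdict(params), indent=2, sort_keys=True)
            )
        manifest["stages"]["dropout_clusters"] = {
            "n_clusters": clusters.n_clusters,
            "sizes": cluster_sizes,
            "n_noise": clusters.n_noise,
            "eps": params.eps,
            "min_pts": params.min_pts,
            "silhouette": params.silhouette,
        }
        results["dropout_clusters"] = clusters

        # ---------------- differential analysis ----------------
        stage = "differential_analysis"
        if config.differential_universe == "all":
            m_diff_linear, m_diff_log = m_filt, m_log
        else:
            m_diff_linear, m_diff_log = m_sel_linear, m_sel_log
        per_cluster = {}
        for lab in sorted(cluster_sizes):
            in_cells = clusters.members(lab)
            tab = analyze_cluster(
                m_diff_linear,
                m_diff_log,
                in_cells,
                lab,
                dropout_threshold=config.dropout_diff,
                logfc_threshold=config.de_logfc,
                p_threshold=config.de_p,
                test=config.de_test,
            )
            per_cluster[lab] = tab
            if outdir is not None:
                tab.to_csv(outdir / f"differential_cluster_{lab}.tsv", sep="\t", index=False)
        pooled, count_table = pool_differential_molecules(per_cluster)
        if outdir is not None:
            count_table.to_csv(outdir / "differential_summary.tsv", sep="\t", index=False)
        manifest["stages"]["differential_analysis"] = {
            "n_differential": len(pooled),
            "counts": count_table.astype(object).to_dict(orient="records"),
        }
        results["differential"] = per_cluster
        results["differential_molecules"] = pooled
        if len(pooled) < 2:
            raise NoClusterStructureError(
                "no cluster structure found: fewer than 2 differential molecules"
            )

        # ---------------- network ----------------
        stage = "network"
        net = build_network(m_diff_log, config.scc, config.scc_p, molecule_ids=pooled)
        if net.number_of_edges() == 0:
            raise NoClusterStructureError(
                "no cluster structure found: empty co-expression network"
            )
        stats = network_stats(net)
        if outdir is not None:
            pd.DataFrame(
                [
                    {"u": u, "v": v, "rho": d["rho"], "weight": d["weight"], "pvalue": d["pvalue"]}
                    for u, v, d in net.edges(data=True)
                ]
            ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        manifest["stages"]["network"] = {
            "n_nodes": stats["n_nodes"],
            "n_edges": stats["n_edges"],
            "n_positive": stats["n_positive"],
            "n_negative": stats["n_negative"],
            "max_abs_rho": round(stats["max_abs_rho"], 6),
        }
        results["network"] = net

        # ---------------- modules ----------------
        stage = "modules"
        modules = mcl_cluster(
            net,
            inflation=config.mcl_inflation,
            expansion=config.mcl_expansion,
            prune=config.mcl_prune,
            max_iter=config.mcl_max_iter,
            tol=config.mcl_tol,
        )
        feats_mod = module_features(m_diff_log, modules)
        if outdir is not None:
            pd.DataFrame(
                [
                    {"module_id": k + 1, "molecule_id": mol}
                    for k, members in enumerate(modules)
                    for mol in sorted(members)
                ]
            ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
            feats_mod.to_frame().to_csv(outdir / "module_features.tsv", sep="\t")
        manifest["stages"]["modules"] = {
            "n_modules": len(modules),
            "sizes": [len(s) for s in modules],
        }
        results["modules"] = modules
        results["module_features"] = feats_mod

        # ---------------- cell types ----------------
        stage = "cell_types"
        try:
            types = assign_cell_types(feats_mod, **_search_kwargs(config))
        except ValueError as exc:
            raise NoClusterStructureError(f"no cluster structure found: {exc}") from exc
        type_sizes = types.sizes()
        if outdir is not None:
            pd.DataFrame(
                {"cell_id": types.cell_ids, "cell_type": types.labels}
            ).to_csv(outdir / "cell_types.tsv", sep="\t", index=False)
        manifest["stages"]["cell_types"] = {
            "n_types": len(types.type_names),
            "sizes": {k: int(v) for k, v in sorted(type_sizes.items())},
            "n_noise": type_sizes.get("0", 0),
        }
        results["cell_types"] = types

        # ---------------- markers ----------------
        stage = "markers"
        marker_matrix = m_sel_log if config.marker_universe == "selected" else m_log
        markers = call_markers(
            marker_matrix,
            types,
            logfc_threshold=config.marker_logfc,
            p_threshold=config.marker_p,
            moderated=config.marker_moderated,
        )
        _, similarity = within_type_similarity(m_sel_log, types)
        if outdir is not None:
            markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
            similarity.to_csv(outdir / "similarity.tsv", sep="\t", index=False)
        manifest["stages"]["markers"] = {
            "n_markers": len(markers),
            "per_type": {
                str(k): int(v)
                for k, v in markers.groupby("cell_type").size().items()
            },
        }
        results["markers"] = markers
        results["similarity"] = similarity
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        if outdir is not None:
            _write_manifest(manifest, outdir)
        if isinstance(exc, (PipelineError, ConfigError)):
            raise
        raise PipelineError(stage, str(exc)) from exc

    if outdir is not None:
        _write_manifest(manifest, outdir)
    return results, manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
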