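"""Reading, writing and quality filtering of expression matrices.

Supports delimited text (CSV/TSV with a header row and an id column) and
MatrixMarket (.mtx) with two sidecar newline-delimited id files.  Molecule
kind annotations (gene vs lncRNA) come from a two-column table; molecules
without an annotation default to ``gene`` with a warning.

Quality control follows standard single-cell practice: molecules detected
in too few cells or with negligible normalized mean expression are dropped,
and cells in which significantly fewer molecules are detected than expected
under a Normal fit to the per-cell detection counts are removed (left-tail
test, Benjamini–Hochberg FDR).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import GENE, LNCRNA, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_kind_table",
    "filter_molecules",
    "filter_cells_by_detection",
    "log_transform",
]


def read_kind_table(path) -> dict[str, str]:
    """Read a two-column (molecule_id, kind) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["molecule_id", "kind"],
                     dtype=str, comment="#")
    kinds = {}
    for mol, kind in zip(df["molecule_id"], df["kind"]):
        if kind not in (GENE, LNCRNA):
            raise ValueError(f"unknown molecule kind {kind!r} for {mol!r}")
        kinds[mol] = kind
    return kinds


def _read_mtx(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    mat = spio.mmread(path)
    values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    rows_file = path.with_suffix(".rows")
    cols_file = path.with_suffix(".cols")
    if not rows_file.exists() or not cols_file.exists():
        raise FileNotFoundError(
            f"MTX sidecar id files not found: {rows_file}, {cols_file}"
        )
    row_ids = rows_file.read_text().split()
    col_ids = cols_file.read_text().split()
    if len(row_ids) != values.shape[0] or len(col_ids) != values.shape[1]:
        raise ValueError(
            f"MTX shape {values.shape} does not match id files "
            f"({len(row_ids)} rows, {len(col_ids)} cols)"
        )
    return values, row_ids, col_ids


def read_expression_matrix(
    path,
    orientation: str = "molecules_rows",
    kind_table=None,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix and normalize it to cells × molecules.

    Parameters
    ----------
    path
        CSV/TSV with header and leading id column, or ``.mtx`` with sidecar
        ``.rows`` / ``.cols`` id files.
    orientation
        ``"molecules_rows"`` (molecules on file rows) or ``"cells_rows"``.
    kind_table
        Optional path to a two-column (molecule_id, kind) TSV, or a dict.
    delimiter
        Forced field delimiter for text input; inferred from the file
        extension otherwise.
    """
    if orientation not in ("molecules_rows", "cells_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix == ".mtx":
        values, row_ids, col_ids = _read_mtx(path)
    else:
        sep = delimiter or ("\t" if path.suffix in (".tsv", ".txt") else ",")
        df = pd.read_csv(path, sep=sep, index_col=0)
        n_missing = int(df.isna().to_numpy().sum())
        if n_missing:
            logger.warning("%d missing entries read as 0 (dropouts)", n_missing)
            df = df.fillna(0.0)
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    if (values < 0).any():
        raise ValueError("negative expression values in input")
    if orientation == "molecules_rows":
        values = values.T
        cell_ids, molecule_ids = col_ids, row_ids
    else:
        cell_ids, molecule_ids = row_ids, col_ids

    kinds = None
    if kind_table is not None:
        mapping = kind_table if isinstance(kind_table, dict) else read_kind_table(kind_table)
        missing = [g for g in molecule_ids if g not in mapping]
        if missing:
            logger.warning(
                "%d molecules lack a kind annotation; defaulting to 'gene'",
                len(missing),
            )
        kinds = np.array([mapping.get(g, GENE) for g in molecule_ids], dtype=object)
    return ExpressionMatrix(values, cell_ids, molecule_ids, kinds)


def write_expression_matrix(m: ExpressionMatrix, path, orientation: str = "molecules_rows") -> None:
    """Write cells × molecules data back out (CSV/TSV or MTX + sidecars)."""
    path = Path(path)
    if path.suffix == ".mtx":
        if orientation == "molecules_rows":
            spio.mmwrite(path, np.asarray(m.values.T))
            path.with_suffix(".rows").write_text("\n".join(m.molecule_ids) + "\n")
            path.with_suffix(".cols").write_text("\n".join(m.cell_ids) + "\n")
        else:
            spio.mmwrite(path, np.asarray(m.values))
            path.with_suffix(".rows").write_text("\n".join(m.cell_ids) + "\n")
            path.with_suffix(".cols").write_text("\n".join(m.molecule_ids) + "\n")
        return
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = m.to_frame()
    if orientation == "molecules_rows":
        df = df.T
    df.to_csv(path, sep=sep)


def write_kind_table(m: ExpressionMatrix, path) -> None:
    pd.DataFrame({"molecule_id": m.molecule_ids, "kind": m.molecule_kind}).to_csv(
        path, sep="\t", header=False, index=False
    )


def filter_molecules(
    m: ExpressionMatrix,
    min_cells: int = 3,
    min_mean_norm: float = 1e-5,
    normalized: bool = True,
) -> ExpressionMatrix:
    """Drop molecules detected in too few cells or with negligible mean.

    A molecule is kept when it is detected (value > 0) in at least
    ``min_cells`` cells AND its mean normalized expression is at least
    ``min_mean_norm``.  Normalized expression of cell i, molecule j is
    ``values[i, j] / total(cell i)`` (per-cell total-count scaling); set
    ``normalized=False`` to threshold the raw mean instead.
    """
    if m.log_transformed:
        raise ValueError("filter_molecules requires linear-scale values")
    detected = (m.values > 0).sum(axis=0)
    totals = m.values.sum(axis=1)
    if normalized:
        zero_cells = totals == 0
        if zero_cells.any():
            warnings.warn(
                f"{int(zero_cells.sum())} cells have zero total expression; "
                "they contribute 0 to normalized means"
            )
        safe = np.where(totals > 0, totals, 1.0)
        norm = m.values / safe[:, None]
        norm[zero_cells, :] = 0.0
        mean_expr = norm.mean(axis=0)
    else:
        mean_expr = m.values.mean(axis=0)
    keep = (detected >= min_cells) & (mean_expr >= min_mean_norm)
    return m.subset_molecules(keep)


def filter_cells_by_detection(
    m: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    by_kind: bool = False,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove cells in which significantly few molecules are detected.

    Fits a Normal distribution (moment estimates, sample sd) to the
    per-cell detected-molecule counts, computes a left-tail p-value per
    cell, BH-adjusts across cells, and removes cells with FDR below the
    threshold.  With ``by_kind=True`` genes and lncRNAs are tested in two
    stratified runs and a cell is removed if flagged in either.

    Returns the filtered matrix and a QC report for every input cell with
    columns ``cell_id, n_detected, pvalue, fdr, removed``.
    """
    if m.n_cells < 3:
        raise ValueError("need at least 3 cells to fit the detection model")

    def _flag(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        counts = binary.sum(axis=1)
        mu = counts.mean()
        sd = counts.std(ddof=1)
        if sd == 0:
            warnings.warn("all cells have identical detection counts; no cell removed")
            pvals = np.ones_like(counts, dtype=float)
            fdrs = np.ones_like(counts, dtype=float)
            return counts, pvals, fdrs
        pvals = stats.norm.cdf(counts, loc=mu, scale=sd)
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        return counts, pvals, fdrs

    detected = m.values > 0
    if by_kind:
        removed = np.zeros(m.n_cells, dtype=bool)
        counts_total = detected.sum(axis=1)
        pv_min = np.ones(m.n_cells)
        fdr_min = np.ones(m.n_cells)
        for kind in (GENE, LNCRNA):
            cols = m.molecule_kind == kind
            if not cols.any():
                continue
            _, pv, fd = _flag(detected[:, cols])
            removed |= fd < fdr_threshold
            pv_min = np.minimum(pv_min, pv)
            fdr_min = np.minimum(fdr_min, fd)
        counts, pvals, fdrs = counts_total, pv_min, fdr_min
    else:
        counts, pvals, fdrs = _flag(detected)
        removed = fdrs < fdr_threshold

    report = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "n_detected": counts.astype(int),
            "pvalue": pvals,
            "fdr": fdrs,
            "removed": removed,
        }
    )
    return m.subset_cells(~removed), report


def log_transform(m: ExpressionMatrix, base: float = 2.0, offset: float = 1.0) -> ExpressionMatrix:
    """Return log_base(values + offset); zeros map exactly to 0 when offset=1."""
    if m.log_transformed:
        raise ValueError("matrix is already log-transformed")
    vals = np.log(m.values + offset) / np.log(base)
    return replace(
        m,
        values=vals,
        cell_ids=list(m.cell_ids),
        molecule_ids=list(m.molecule_ids),
        molecule_kind=m.molecule_kind.copy(),
        log_transformed=True,
    )
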