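"""Core in-memory container for cells × molecules expression data.

The whole pipeline operates on a single substrate: a dense non-negative
matrix of expression values with cells on the rows and molecules (protein-
coding genes or lncRNAs) on the columns.  Values are on the linear scale
until :func:`celldrop.io.log_transform` is applied, after which the
``log_transformed`` flag is set and dropout-based operations refuse to run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

GENE = "gene"
LNCRNA = "lncRNA"
VALID_KINDS = (GENE, LNCRNA)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """Cells × molecules expression values with molecule kind labels.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_cells, n_molecules)``, non-negative,
        no NaN (missing entries must be converted to 0 before construction).
    cell_ids, molecule_ids
        Unique identifiers matching the matrix dimensions.
    molecule_kind
        Per-molecule label, each ``"gene"`` or ``"lncRNA"``.
    log_transformed
        True once values are log2(x+1)-scale.
    """

    values: np.ndarray
    cell_ids: list[str]
    molecule_ids: list[str]
    molecule_kind: np.ndarray = field(default=None)  # type: ignore[assignment]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.molecule_ids = [str(g) for g in self.molecule_ids]
        n_cells, n_mol = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.molecule_ids) != n_mol:
            raise ValueError(
                f"{len(self.molecule_ids)} molecule ids for {n_mol} matrix columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.molecule_ids, "molecule")
        if np.isnan(self.values).any():
            raise ValueError("NaN entries in expression values")
        if (self.values < 0).any():
            raise ValueError("negative expression values")
        if self.molecule_kind is None:
            self.molecule_kind = np.full(n_mol, GENE, dtype=object)
        else:
            self.molecule_kind = np.asarray(self.molecule_kind, dtype=object)
            if self.molecule_kind.shape != (n_mol,):
                raise ValueError("molecule_kind length must match molecule count")
            bad = set(self.molecule_kind) - set(VALID_KINDS)
            if bad:
                raise ValueError(f"invalid molecule kinds: {sorted(bad)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.values.shape[1]

    def cell_index(self, cell_ids: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise KeyError(f"unknown cell ids: {missing[:10]}")
        return np.array([lookup[c] for c in cell_ids], dtype=int)

    def molecule_index(self, molecule_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.molecule_ids)}
        missing = [g for g in molecule_ids if g not in lookup]
        if missing:
            raise KeyError(f"unknown molecule ids: {missing[:10]}")
        return np.array([lookup[g] for g in molecule_ids], dtype=int)

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        idx = self._as_index(mask_or_ids, self.n_cells, axis="cells")
        return replace(
            self,
            values=self.values[idx, :],
            cell_ids=[self.cell_ids[i] for i in idx],
            molecule_ids=list(self.molecule_ids),
            molecule_kind=self.molecule_kind.copy(),
        )

    def subset_molecules(self, mask_or_ids) -> "ExpressionMatrix":
        idx = self._as_index(mask_or_ids, self.n_molecules, axis="molecules")
        return replace(
            self,
            values=self.values[:, idx],
            cell_ids=list(self.cell_ids),
            molecule_ids=[self.molecule_ids[i] for i in idx],
            molecule_kind=self.molecule_kind[idx],
        )

    def _as_index(self, mask_or_ids, n: int, axis: str) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            if arr.shape != (n,):
                raise ValueError(f"boolean mask length must match number of {axis}")
            return np.flatnonzero(arr)
        if arr.dtype.kind in "iu":
            return arr.astype(int)
        # fall back: ids
        if axis == "cells":
            return self.cell_index(list(arr))
        return self.molecule_index(list(arr))

    def to_frame(self) -> pd.DataFrame:
        """Cells × molecules DataFrame view (copy)."""
        return pd.DataFrame(
            self.values, index=self.cell_ids, columns=self.molecule_ids
        )

    def kind_of(self, molecule_id: str) -> str:
        return str(self.molecule_kind[self.molecule_index([molecule_id])[0]])
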