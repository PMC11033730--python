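"""Sparse binary interaction matrices (drug-target and drug-drug).

Backed by scipy CSR with explicit row/column id labels.  The DDI variant is
a symmetric drug-drug adjacency with an empty diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


@dataclass
class InteractionMatrix:
    row_ids: list[str]
    col_ids: list[str]
    matrix: sp.csr_matrix  # binary
    kind: str  # "DTI" | "DDI"

    def __post_init__(self) -> None:
        if self.kind not in ("DTI", "DDI"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.matrix.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id labels")
        if self.kind == "DDI":
            if self.row_ids != self.col_ids:
                raise ValueError("DDI matrix must have identical row and column ids")
            if (self.matrix != self.matrix.T).nnz != 0:
                raise ValueError("DDI matrix must be symmetric")
            if self.matrix.diagonal().sum() != 0:
                raise ValueError("DDI matrix must have an empty diagonal")
        data = self.matrix.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("interaction matrix entries must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_index(self, drug_id: str) -> int:
        try:
            return self.row_ids.index(drug_id)
        except ValueError:
            raise KeyError(drug_id) from None

    def has_row(self, drug_id: str) -> bool:
        return drug_id in set(self.row_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense(), dtype=float)


def from_entries(
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    entries: Iterable[tuple[str, str]],
    kind: str,
) -> InteractionMatrix:
    """Build a matrix from (row_id, col_id) pairs; DDI pairs are symmetrized."""
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: j for j, c in enumerate(col_ids)}
    rows, cols = [], []
    for r, c in entries:
        i, j = ri[r], ci[c]
        if kind == "DDI":
            if i == j:
                continue
            rows.extend((i, j))
            cols.extend((j, i))
        else:
            rows.append(i)
            cols.append(j)
    mat = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(row_ids), len(col_ids))
    ).tocsr()
    mat.data[:] = 1.0  # collapse duplicates
    return InteractionMatrix(list(row_ids), list(col_ids), mat, kind)


def write_triplets(im: InteractionMatrix, path: str | Path) -> None:
    """TSV triplets `row_id<TAB>col_id<TAB>1`, plus `<path>.rows` / `.cols`
    sidecar id lists fixing the axis order."""
    path = Path(path)
    coo = im.matrix.tocoo()
    with open(path, "w") as fh:
        for i, j in sorted(zip(coo.row.tolist(), coo.col.tolist())):
            fh.write(f"{im.row_ids[i]}\t{im.col_ids[j]}\t1\n")
    Path(str(path) + ".rows").write_text("\n".join(im.row_ids) + "\n")
    Path(str(path) + ".cols").write_text("\n".join(im.col_ids) + "\n")


def read_triplets(path: str | Path, kind: str) -> InteractionMatrix:
    path = Path(path)
    row_ids = Path(str(path) + ".rows").read_text().splitlines()
    col_ids = Path(str(path) + ".cols").read_text().splitlines()
    entries = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            r, c, _ = line.rstrip("\n").split("\t")
            entries.append((r, c))
    return from_entries(row_ids, col_ids, entries, kind)


def _mtx_path(path: str | Path) -> Path:
    path = Path(path)
    return path if path.suffix == ".mtx" else path.with_suffix(path.suffix + ".mtx")


def write_matrixmarket(im: InteractionMatrix, path: str | Path) -> None:
    path = _mtx_path(path)
    mmwrite(str(path), im.matrix.tocoo())
    Path(str(path) + ".rows").write_text("\n".join(im.row_ids) + "\n")
    Path(str(path) + ".cols").write_text("\n".join(im.col_ids) + "\n")


def read_matrixmarket(path: str | Path, kind: str) -> InteractionMatrix:
    path = _mtx_path(path)
    mat = sp.csr_matrix(mmread(str(path)))
    row_ids = Path(str(path) + ".rows").read_text().splitlines()
    col_ids = Path(str(path) + ".cols").read_text().splitlines()
    return InteractionMatrix(row_ids, col_ids, mat, kind)
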