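"""Count-matrix containers and readers/writers.

The pipeline consumes deduplicated UMI count matrices (cells × genes), either
as Matrix Market triplets with companion ``barcodes.tsv``/``features.tsv``
files (the 10x/inDrop convention, stored genes × cells on disk) or as a dense
CSV with a header row of gene identifiers.  Orientation of MTX input is
resolved by matching matrix dimensions against the companion-file lengths.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["CountMatrix", "NormalizedMatrix", "read_counts", "write_counts"]


class FormatError(ValueError):
    """Raised when an on-disk matrix and its companion files disagree."""


@dataclass
class CountMatrix:
    """Sparse cells × genes UMI counts with per-cell metadata.

    ``cell_meta`` is indexed like ``cell_ids`` and carries at least
    ``condition`` (control / EoE / ESCC) and ``replicate`` columns when the
    matrix feeds the downstream statistics.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        nc, ng = self.counts.shape
        if len(self.cell_ids) != nc:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for a matrix with {nc} rows"
            )
        if len(self.gene_ids) != ng:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for a matrix with {ng} columns"
            )
        if len(set(self.cell_ids)) != nc:
            raise ValueError("cell ids are not unique")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("gene ids are not unique")
        if len(self.cell_meta) != nc:
            raise FormatError("cell_meta length does not match cell count")
        data = self.counts.data
        if data.size:
            if (data < 0).any():
                raise ValueError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts contain non-integer entries")

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.iloc[idx].copy(),
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[idx],
            cell_meta=self.cell_meta.copy(),
        )

    def gene_index(self, gene: str) -> int:
        """Index of ``gene``, with a case-insensitive fallback suggestion."""
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size:
            return int(hits[0])
        lower = np.char.lower(self.gene_ids.astype(str))
        near = np.flatnonzero(lower == gene.lower())
        if near.size:
            raise KeyError(
                f"gene {gene!r} not found; did you mean {self.gene_ids[near[0]]!r}?"
            )
        raise KeyError(f"gene {gene!r} not found in matrix")


@dataclass
class NormalizedMatrix:
    """Dense cells × genes normalized log10 expression (zeros map to zero)."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("normalized matrix shape does not match id vectors")

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size:
            return int(hits[0])
        lower = np.char.lower(self.gene_ids.astype(str))
        near = np.flatnonzero(lower == gene.lower())
        if near.size:
            raise KeyError(
                f"gene {gene!r} not found; did you mean {self.gene_ids[near[0]]!r}?"
            )
        raise KeyError(f"gene {gene!r} not found in matrix")


# ----------------------------------------------------------------------
def _read_lines(path: Path) -> list[str]:
    return [ln.split("\t")[0].strip() for ln in path.read_text().splitlines() if ln.strip()]


def read_counts(
    path: str | Path,
    fmt: str | None = None,
    barcodes: str | Path | None = None,
    features: str | Path | None = None,
    meta: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from MTX (+ barcodes/features TSV) or dense CSV.

    For MTX input, cells always end up as rows: if the stored matrix is
    genes × cells (the common convention) it is transposed, with orientation
    decided by matching each dimension against the companion-file lengths.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix in {".mtx", ".mm"} else "csv"

    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        counts = df.to_numpy()
        if counts.size and ((counts < 0).any() or not np.allclose(counts, np.round(counts))):
            raise ValueError(f"{path}: CSV counts must be nonnegative integers")
        cm = CountMatrix(
            counts=sp.csr_matrix(counts.astype(np.int64)),
            cell_ids=df.index.to_numpy(dtype=object),
            gene_ids=df.columns.to_numpy(dtype=object),
        )
    elif fmt == "mtx":
        barcodes = Path(barcodes) if barcodes else path.with_name("barcodes.tsv")
        features = Path(features) if features else path.with_name("features.tsv")
        cell_ids = _read_lines(barcodes)
        gene_ids = _read_lines(features)
        mat = sp.csr_matrix(mmread(path))
        nr, nc = mat.shape
        if (nr, nc) == (len(cell_ids), len(gene_ids)):
            pass  # already cells x genes
        elif (nr, nc) == (len(gene_ids), len(cell_ids)):
            mat = mat.T.tocsr()
        else:
            raise FormatError(
                f"{path}: matrix is {nr}x{nc} but companions give "
                f"{len(cell_ids)} barcodes and {len(gene_ids)} features"
            )
        if mat.data.size and ((mat.data < 0).any() or not np.allclose(mat.data, np.round(mat.data))):
            raise ValueError(f"{path}: MTX counts must be nonnegative integers")
        cm = CountMatrix(
            counts=mat.astype(np.int64),
            cell_ids=np.array(cell_ids, dtype=object),
            gene_ids=np.array(gene_ids, dtype=object),
        )
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'mtx' or 'csv')")

    if meta is not None:
        meta_df = pd.read_csv(meta, index_col=0)
        meta_df.index = meta_df.index.astype(object)
        cm.cell_meta = meta_df.loc[cm.cell_ids]
    return cm


def write_counts(cm: CountMatrix, out_dir: str | Path, stem: str = "counts") -> dict[str, Path]:
    """Write MTX + barcodes.tsv + features.tsv (+ metadata CSV); returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / f"{stem}.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "meta": out / f"{stem}_meta.csv",
    }
    # store genes x cells, the on-disk convention
    mmwrite(paths["mtx"], cm.counts.T.tocoo(), field="integer")
    paths["barcodes"].write_text("\n".join(map(str, cm.cell_ids)) + "\n")
    paths["features"].write_text("\n".join(map(str, cm.gene_ids)) + "\n")
    cm.cell_meta.to_csv(paths["meta"], index_label="cell_id")
    return paths
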