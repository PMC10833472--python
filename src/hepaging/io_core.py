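"""Core data model, 10x-style Matrix Market IO, QC filtering, and normalization.

The count matrix is stored genes x cells (10x convention). All readers and
writers use plain-text formats: coordinate-integer ``.mtx`` plus one-id-per-line
``genes.tsv`` / ``barcodes.tsv``, and tab-separated tables with headers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "QCReport",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_cell_meta",
    "write_cell_meta",
    "annotate_cell_meta",
    "qc_filter",
    "normalize_log1p_cp10k",
    "read_gmt",
    "write_gmt",
]

VALID_GROUPS = ("young", "aged")


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI matrix, genes as rows, cells as columns."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell ids are not unique")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise FormatError("count matrix contains negative entries")
            if not np.allclose(data, np.round(data)):
                raise FormatError("count matrix contains non-integer entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def total_umi(self) -> np.ndarray:
        """Per-cell UMI totals."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 in each cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def pct_mito(self, mito_gene_prefix: str = "MT-") -> np.ndarray:
        """Fraction of each cell's UMIs on genes whose id starts with the prefix."""
        mito = np.array(
            [g.startswith(mito_gene_prefix) for g in self.gene_ids], dtype=bool
        )
        totals = self.total_umi().astype(float)
        mito_counts = np.asarray(self.counts[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        return frac

    def subset_cells(self, cell_ids: list[str]) -> "CountMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [index[c] for c in cell_ids]
        return CountMatrix(self.counts[:, cols], list(self.gene_ids), list(cell_ids))

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return CountMatrix(self.counts[rows], list(gene_ids), list(self.cell_ids))


@dataclass
class NormalizedMatrix:
    """log1p of counts-per-``scale`` expression, genes x cells."""

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    scale: float = 1e4

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("normalized matrix shape does not match id lists")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def subset_cells(self, cell_ids: list[str]) -> "NormalizedMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [index[c] for c in cell_ids]
        return NormalizedMatrix(
            self.values[:, cols], list(self.gene_ids), list(cell_ids), self.scale
        )

    def subset_genes(self, gene_ids: list[str]) -> "NormalizedMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return NormalizedMatrix(
            self.values[rows], list(gene_ids), list(self.cell_ids), self.scale
        )


@dataclass
class QCReport:
    """Counts of cells passing / failing each QC rule (rules counted independently)."""

    n_input_cells: int
    n_pass_cells: int
    n_fail_min_genes: int
    n_fail_mito: int
    min_genes: int = 200
    max_pct_mito: float = 0.05
    mito_gene_prefix: str = "MT-"

    def to_dict(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_pass_cells": self.n_pass_cells,
            "n_fail_min_genes": self.n_fail_min_genes,
            "n_fail_mito": self.n_fail_mito,
            "min_genes": self.min_genes,
            "max_pct_mito": self.max_pct_mito,
            "mito_gene_prefix": self.mito_gene_prefix,
        }


def _read_id_column(path: str | Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_counts(
    mtx_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> CountMatrix:
    """Read a Matrix Market triplet (matrix + gene ids + cell barcodes).

    Genes are rows and cells columns in the ``.mtx`` file; the gene file may
    carry an optional second symbol column which is ignored.
    """
    mat = scipy.io.mmread(str(mtx_path))
    genes = _read_id_column(genes_path)
    cells = _read_id_column(barcodes_path)
    n_genes, n_cells = mat.shape
    if n_genes != len(genes):
        raise FormatError(
            f"{mtx_path} declares {n_genes} gene rows but {genes_path} "
            f"lists {len(genes)} ids"
        )
    if n_cells != len(cells):
        raise FormatError(
            f"{mtx_path} declares {n_cells} cell columns but {barcodes_path} "
            f"lists {len(cells)} ids"
        )
    mat = sp.csr_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx_path} contains non-integer entries")
    return CountMatrix(mat.astype(np.int64), genes, cells)


def write_counts(
    cm: CountMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write a CountMatrix back as mtx + id files (exact round-trip)."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts), field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in cm.gene_ids))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in cm.cell_ids))


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated cell metadata table.

    Requires columns cell_id, sample_id, group; cell_type is optional.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "sample_id", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"cell meta missing columns: {sorted(missing)}")
    bad = set(meta["group"]) - set(VALID_GROUPS)
    if bad:
        raise FormatError(f"invalid group labels {sorted(bad)}; expected {VALID_GROUPS}")
    if meta["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id in cell meta")
    return meta


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def annotate_cell_meta(
    cm: CountMatrix, meta: pd.DataFrame, mito_gene_prefix: str = "MT-"
) -> pd.DataFrame:
    """Attach per-cell n_genes, total_umi, and pct_mito computed from the matrix."""
    covered = set(meta["cell_id"])
    uncovered = [c for c in cm.cell_ids if c not in covered]
    if uncovered:
        raise FormatError(
            f"cell meta does not cover {len(uncovered)} cells "
            f"(first missing: {uncovered[0]})"
        )
    meta = meta.set_index("cell_id").loc[cm.cell_ids].reset_index()
    meta["n_genes"] = cm.genes_per_cell()
    meta["total_umi"] = cm.total_umi()
    meta["pct_mito"] = cm.pct_mito(mito_gene_prefix)
    return meta


def qc_filter(
    cm: CountMatrix,
    meta: pd.DataFrame,
    min_genes: int = 200,
    max_pct_mito: float = 0.05,
    mito_gene_prefix: str = "MT-",
) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Remove low-quality cells.

    Cells are retained when they detect at least ``min_genes`` genes and their
    mitochondrial UMI fraction does not exceed ``max_pct_mito`` (a cell at
    exactly the threshold is kept; only "more than" fails). Failure counts are
    reported per rule, evaluated independently, so a cell failing both rules
    increments both counters.
    """
    n_genes = cm.genes_per_cell()
    pct_mito = cm.pct_mito(mito_gene_prefix)
    fail_genes = n_genes < min_genes
    fail_mito = pct_mito > max_pct_mito
    keep = ~(fail_genes | fail_mito)
    report = QCReport(
        n_input_cells=cm.n_cells,
        n_pass_cells=int(keep.sum()),
        n_fail_min_genes=int(fail_genes.sum()),
        n_fail_mito=int(fail_mito.sum()),
        min_genes=min_genes,
        max_pct_mito=max_pct_mito,
        mito_gene_prefix=mito_gene_prefix,
    )
    kept_ids = [c for c, k in zip(cm.cell_ids, keep) if k]
    if not kept_ids:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
        empty = CountMatrix(
            sp.csr_matrix((cm.n_genes, 0), dtype=np.int64), list(cm.gene_ids), []
        )
        return empty, meta.iloc[0:0].copy(), report
    out = cm.subset_cells(kept_ids)
    meta_out = meta[meta["cell_id"].isin(set(kept_ids))].copy()
    meta_out = meta_out.set_index("cell_id").loc[kept_ids].reset_index()
    return out, meta_out, report


def normalize_log1p_cp10k(cm: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """value(g, c) = ln(1 + count(g, c) * scale / total_umi(c)), natural log."""
    totals = cm.total_umi().astype(float)
    if (totals == 0).any():
        n_zero = int((totals == 0).sum())
        raise ValueError(
            f"{n_zero} cells have zero total UMI; run qc_filter before normalizing"
        )
    mat = sp.csc_matrix(cm.counts, dtype=float)
    # scale each column by scale / total, then log1p; sparsity is preserved
    mat = mat @ sp.diags(scale / totals)
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(sp.csr_matrix(mat), list(cm.gene_ids), list(cm.cell_ids), scale)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                continue
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
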