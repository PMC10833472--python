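"""Transcriptional-noise pipeline.

Sequencing depth is equalized by multivariate-hypergeometric UMI
down-sampling, cell-type group sizes are balanced, and each cell's noise is
its Euclidean distance to the mean normalized expression vector of its
(cell type, age group), restricted to genes detected in a minimum fraction of
the cell type's cells. Summaries are aged/young log2 median ratios with
rank-sum p-values, BH-adjusted across cell types.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import t as t_dist

from .deg import bh_adjust, rank_sum_p
from .io_core import CountMatrix, NormalizedMatrix, normalize_log1p_cp10k

__all__ = [
    "downsample_umi",
    "default_target_umi",
    "balance_groups",
    "transcriptional_noise",
    "noise_ratio",
    "noise_correlated_genes",
    "bin_by_noise",
]


def downsample_umi(cm: CountMatrix, target_umi: int, seed: int = 0) -> CountMatrix:
    """Down-sample every cell to exactly ``target_umi`` UMIs without replacement.

    Cells whose total is below the target are dropped; a cell exactly at the
    target keeps its counts. Each retained cell's counts are replaced by a
    multivariate-hypergeometric draw of ``target_umi`` UMIs from its observed
    UMIs, so every output entry is bounded by the input entry.
    """
    if target_umi < 1:
        raise ValueError("target_umi must be >= 1")
    totals = cm.total_umi()
    keep = totals >= target_umi
    if not keep.any():
        warnings.warn(
            f"no cell reaches target_umi={target_umi}; result is empty", stacklevel=2
        )
        return CountMatrix(
            sp.csr_matrix((cm.n_genes, 0), dtype=np.int64), list(cm.gene_ids), []
        )
    rng = np.random.default_rng(seed)
    csc = sp.csc_matrix(cm.counts)
    kept_ids = [c for c, k in zip(cm.cell_ids, keep) if k]
    cols = np.flatnonzero(keep)
    data, indices, indptr = [], [], [0]
    for j in cols:
        start, end = csc.indptr[j], csc.indptr[j + 1]
        rows = csc.indices[start:end]
        vals = csc.data[start:end].astype(np.int64)
        if totals[j] == target_umi:
            drawn = vals
        else:
            drawn = rng.multivariate_hypergeometric(vals, target_umi)
        nz = drawn > 0
        indices.append(rows[nz])
        data.append(drawn[nz])
        indptr.append(indptr[-1] + int(nz.sum()))
    out = sp.csc_matrix(
        (
            np.concatenate(data) if data else np.array([], dtype=np.int64),
            np.concatenate(indices) if indices else np.array([], dtype=np.int32),
            np.array(indptr),
        ),
        shape=(cm.n_genes, len(cols)),
    )
    return CountMatrix(sp.csr_matrix(out), list(cm.gene_ids), kept_ids)


def default_target_umi(cm: CountMatrix, floor: int = 1000) -> int:
    """Minimum cell total, capped below at ``floor`` (cells under it get dropped)."""
    totals = cm.total_umi()
    if totals.size == 0:
        raise ValueError("empty matrix")
    return int(max(floor, totals[totals >= floor].min() if (totals >= floor).any() else floor))


def balance_groups(
    meta: pd.DataFrame,
    seed: int = 0,
    min_cells: int = 20,
    cell_type_col: str = "cell_type",
) -> list[str]:
    """Equal-size young/aged subsample per cell type.

    Per cell type, m = min(n_young, n_aged) cells are drawn uniformly without
    replacement from each group; cell types with m < ``min_cells`` are dropped
    with a warning. Returns selected cell ids.
    """
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for ct in sorted(meta[cell_type_col].dropna().unique()):
        sub = meta[meta[cell_type_col] == ct]
        young = sub.loc[sub["group"] == "young", "cell_id"].to_numpy()
        aged = sub.loc[sub["group"] == "aged", "cell_id"].to_numpy()
        m = min(len(young), len(aged))
        if m < min_cells:
            warnings.warn(
                f"cell type {ct!r} has only {m} cells in the smaller group "
                f"(min_cells={min_cells}); excluded",
                stacklevel=2,
            )
            continue
        for pool in (young, aged):
            if len(pool) == m:
                selected.extend(pool.tolist())
            else:
                selected.extend(rng.choice(pool, size=m, replace=False).tolist())
    return selected


def transcriptional_noise(
    cm: CountMatrix,
    meta: pd.DataFrame,
    gene_min_pct: float = 0.1,
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Per-cell distance-to-centroid noise on balanced, down-sampled counts.

    Counts are log1p-CP10K normalized; within each cell type the gene space is
    restricted to genes detected in >= ``gene_min_pct`` of that type's cells;
    noise(c) is the Euclidean distance of c to its (cell type, group) centroid.
    """
    nm = normalize_log1p_cp10k(cm)
    meta_idx = meta.set_index("cell_id")
    labels = meta_idx.loc[nm.cell_ids]
    rows = []
    for ct in sorted(labels[cell_type_col].dropna().unique()):
        cell_mask = (labels[cell_type_col] == ct).to_numpy()
        cells = np.asarray(nm.cell_ids)[cell_mask]
        block = nm.values[:, np.flatnonzero(cell_mask)]
        detected = np.asarray((block > 0).mean(axis=1)).ravel() >= gene_min_pct
        dense = block[np.flatnonzero(detected)].toarray()
        groups = labels.loc[cells, "group"].to_numpy()
        for group in ("young", "aged"):
            g_mask = groups == group
            if not g_mask.any():
                continue
            if g_mask.sum() == 1:
                warnings.warn(
                    f"cell type {ct!r}, group {group!r} has a single cell; "
                    "noise is degenerately 0",
                    stacklevel=2,
                )
            sub = dense[:, g_mask]
            centroid = sub.mean(axis=1, keepdims=True)
            dist = np.sqrt(((sub - centroid) ** 2).sum(axis=0))
            for cid, d in zip(cells[g_mask], dist):
                rows.append(
                    {"cell_id": cid, "cell_type": ct, "group": group, "noise": float(d)}
                )
    out = pd.DataFrame(rows, columns=["cell_id", "cell_type", "group", "noise"])
    out.attrs["gene_min_pct"] = gene_min_pct
    return out


def noise_ratio(noise_table: pd.DataFrame) -> pd.DataFrame:
    """Per cell type: log2(median aged / median young) noise, rank-sum p, BH."""
    rows = []
    for ct, grp in noise_table.groupby("cell_type", sort=True):
        young = grp.loc[grp["group"] == "young", "noise"].to_numpy()
        aged = grp.loc[grp["group"] == "aged", "noise"].to_numpy()
        if len(young) == 0 or len(aged) == 0:
            continue
        med_y, med_a = float(np.median(young)), float(np.median(aged))
        if med_y == 0.0:
            rows.append(
                {
                    "cell_type": ct,
                    "log2_ratio": np.nan,
                    "p": np.nan,
                    "n_young": len(young),
                    "n_aged": len(aged),
                    "note": "young median is 0; ratio undefined",
                }
            )
            continue
        rows.append(
            {
                "cell_type": ct,
                "log2_ratio": float(np.log2(med_a / med_y)),
                "p": rank_sum_p(aged, young),
                "n_young": len(young),
                "n_aged": len(aged),
                "note": "",
            }
        )
    out = pd.DataFrame(
        rows, columns=["cell_type", "log2_ratio", "p", "n_young", "n_aged", "note"]
    )
    if len(out):
        valid = out["p"].notna()
        out["p_adj"] = np.nan
        out.loc[valid, "p_adj"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out


def noise_correlated_genes(
    nm: NormalizedMatrix,
    noise_table: pd.DataFrame,
    cell_type: str,
    r_min: float = 0.6,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with per-cell noise.

    Both age groups of the cell type are pooled. p-values come from the
    t-transform of r; BH over tested genes; ``selected`` flags |r| > r_min
    (strict) and fdr < fdr_max. Constant genes are excluded (count in attrs).
    """
    sub = noise_table[noise_table["cell_type"] == cell_type]
    cells = [c for c in sub["cell_id"] if c in set(nm.cell_ids)]
    if len(cells) < 3:
        raise ValueError(f"cell type {cell_type!r}: fewer than 3 cells with noise values")
    noise = sub.set_index("cell_id").loc[cells, "noise"].to_numpy()
    dense = nm.subset_cells(cells).dense()
    n = len(cells)

    x = dense - dense.mean(axis=1, keepdims=True)
    y = noise - noise.mean()
    sx = np.sqrt((x**2).sum(axis=1))
    sy = np.sqrt((y**2).sum())
    variable = (sx > 0) & (sy > 0)
    n_constant = int((~variable).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ y) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    idx = np.flatnonzero(variable)
    r = r[idx]
    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * t_dist.sf(np.abs(t_stat), df=n - 2)
    p = np.minimum(p, 1.0)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": np.asarray(nm.gene_ids)[idx],
            "pearson_r": r,
            "p": p,
            "fdr": fdr,
            "direction": np.where(r >= 0, "positive", "negative"),
            "selected": (np.abs(r) > r_min) & (fdr < fdr_max),
        }
    )
    out.attrs["n_constant_excluded"] = n_constant
    out.attrs["cell_type"] = cell_type
    return out


def bin_by_noise(noise_table: pd.DataFrame, n_bins: int = 20) -> pd.Series:
    """Equal-frequency noise-rank bins within each (cell type, group).

    Ties break deterministically by cell_id. Returns bin index (0-based) per cell.
    """
    out = pd.Series(index=noise_table["cell_id"], dtype=int, name="bin")
    for (_, _), grp in noise_table.groupby(["cell_type", "group"], sort=True):
        if n_bins > len(grp):
            raise ValueError(
                f"n_bins={n_bins} exceeds group size {len(grp)}"
            )
        ordered = grp.sort_values(["noise", "cell_id"], kind="mergesort")
        ranks = np.arange(len(ordered))
        out.loc[ordered["cell_id"]] = ranks * n_bins // len(ordered)
    return out
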