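"""Gene-set module scores, young-marker cell-identity scoring, and zonation labels.

The module score follows the binned-control scheme: genes are cut into
equal-frequency bins of mean expression, each set gene draws control genes
from its own bin, and the score is the set mean minus the control mean per
cell. Zonation labels come from terciles of the pericentral-minus-periportal
score axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import deg as deg_mod
from .io_core import NormalizedMatrix

__all__ = [
    "GeneSet",
    "ScoreVector",
    "module_score",
    "young_identity_sets",
    "identity_drift",
    "zonation_assign",
]


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    signs: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class ScoreVector:
    name: str
    scores: pd.Series  # cell_id -> score
    params: dict = field(default_factory=dict)


def module_score(
    nm: NormalizedMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ScoreVector:
    """Binned-control expression score of a gene set for every cell.

    Genes are ranked by mean expression over all cells and split into
    ``n_bins`` equal-frequency bins (stable ties by matrix gene order). For
    each set gene, ``n_ctrl`` controls are drawn uniformly with replacement
    from its bin; score(c) = mean over set genes of value(g, c) minus the mean
    over all drawn control genes of value(g', c).
    """
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    present = [g for g in gene_set.genes if g in gene_index]
    missing = [g for g in gene_set.genes if g not in gene_index]
    if missing:
        warnings.warn(
            f"gene set {gene_set.name!r}: {len(missing)} genes absent from matrix",
            stacklevel=2,
        )
    if not present:
        raise ValueError(
            f"gene set {gene_set.name!r} has no genes in the matrix "
            f"(missing: {missing[:5]}...)"
        )
    n_genes = nm.shape[0]
    if n_bins > n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes {n_genes}")

    dense = nm.dense()
    means = dense.mean(axis=1)
    # rank by (mean, gene id) so binning and control pools do not depend on
    # the order genes happen to appear in the matrix
    gene_names = np.asarray(nm.gene_ids)
    order = np.lexsort((gene_names, means))
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.arange(n_genes) * n_bins // n_genes
    bins: dict[int, np.ndarray] = {}
    for b in range(n_bins):
        pool = np.flatnonzero(bin_of == b)
        bins[b] = pool[np.argsort(gene_names[pool], kind="mergesort")]

    rng = np.random.default_rng(seed)
    set_rows = np.array([gene_index[g] for g in present])
    ctrl_rows: list[np.ndarray] = []
    for row in set_rows:
        pool = bins[bin_of[row]]
        ctrl_rows.append(pool[rng.integers(0, len(pool), size=n_ctrl)])
    ctrl = np.concatenate(ctrl_rows)
    scores = dense[set_rows].mean(axis=0) - dense[ctrl].mean(axis=0)
    return ScoreVector(
        name=gene_set.name,
        scores=pd.Series(scores, index=nm.cell_ids, name=gene_set.name),
        params={"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed},
    )


def young_identity_sets(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    top_n: int = 50,
    lfc_min: float = 0.5,
    padj_max: float = 0.05,
    min_pct: float = 0.1,
    cell_type_col: str = "cell_type",
) -> dict[str, GeneSet]:
    """Top marker genes per cell type, computed on young cells only.

    One-vs-rest rank-sum per cell type; genes kept at avg_log2FC >= lfc_min
    and BH-adjusted p <= padj_max, ranked by fold change descending (ties
    broken lexicographically by gene id), truncated to top_n.
    """
    young = meta[meta["group"] == "young"]
    types = sorted(young[cell_type_col].dropna().unique())
    young_nm = nm.subset_cells(young["cell_id"].tolist())
    dense = young_nm.dense()
    type_labels = young.set_index("cell_id").loc[young_nm.cell_ids, cell_type_col].to_numpy()
    genes = np.asarray(young_nm.gene_ids)

    sets: dict[str, GeneSet] = {}
    for ct in types:
        in_type = type_labels == ct
        if in_type.sum() < 3:
            warnings.warn(
                f"cell type {ct!r} has {int(in_type.sum())} young cells (<3); skipped",
                stacklevel=2,
            )
            continue
        x_t = dense[:, in_type]
        x_r = dense[:, ~in_type]
        pct_t = (x_t > 0).mean(axis=1)
        pct_r = (x_r > 0).mean(axis=1)
        lfc = deg_mod.avg_log2fc(x_t, x_r)
        tested = ((pct_t >= min_pct) | (pct_r >= min_pct)) & (lfc >= lfc_min)
        idx = np.flatnonzero(tested)
        if idx.size == 0:
            warnings.warn(f"cell type {ct!r}: no candidate marker genes", stacklevel=2)
            continue
        pvals = np.array([deg_mod.rank_sum_p(x_t[i], x_r[i]) for i in idx])
        padj = deg_mod.bh_adjust(pvals)
        keep = padj <= padj_max
        ranked = sorted(
            zip(-lfc[idx][keep], genes[idx][keep]), key=lambda t: (t[0], t[1])
        )
        chosen = [g for _, g in ranked[:top_n]]
        if not chosen:
            warnings.warn(f"cell type {ct!r}: no significant marker genes", stacklevel=2)
            continue
        if len(chosen) < top_n:
            warnings.warn(
                f"cell type {ct!r}: only {len(chosen)} markers available "
                f"(requested {top_n})",
                stacklevel=2,
            )
        sets[ct] = GeneSet(name=ct, genes=chosen)
    return sets


def identity_drift(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    sets: dict[str, GeneSet],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Aged-vs-young shift of each cell type's identity score.

    Scores all cells with that type's young-marker set, compares groups within
    the cell type by two-sided rank-sum, BH across cell types.
    """
    meta_idx = meta.set_index("cell_id")
    rows = []
    for ct, gene_set in sets.items():
        sv = module_score(nm, gene_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        cells = meta.loc[meta[cell_type_col] == ct, "cell_id"]
        scores = sv.scores.loc[cells]
        groups = meta_idx.loc[cells, "group"]
        young_scores = scores[groups == "young"].to_numpy()
        aged_scores = scores[groups == "aged"].to_numpy()
        p = (
            deg_mod.rank_sum_p(aged_scores, young_scores)
            if len(young_scores) and len(aged_scores)
            else np.nan
        )
        rows.append(
            {
                "cell_type": ct,
                "mean_score_young": float(young_scores.mean()) if len(young_scores) else np.nan,
                "mean_score_aged": float(aged_scores.mean()) if len(aged_scores) else np.nan,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["drift"] = out["mean_score_aged"] - out["mean_score_young"]
        valid = out["p"].notna()
        out["p_adj"] = np.nan
        out.loc[valid, "p_adj"] = deg_mod.bh_adjust(out.loc[valid, "p"].to_numpy())
    return out


def zonation_assign(
    nm: NormalizedMatrix,
    cell_ids: list[str],
    pp_set: GeneSet,
    pc_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Tercile zonation labels (PP / MZ / PC) along the PC-minus-PP score axis.

    d(c) = module_score(pc) - module_score(pp); cells strictly below the lower
    tercile of d are PP, strictly above the upper tercile PC, the rest
    (boundaries included) MZ.
    """
    if len(cell_ids) < 3:
        raise ValueError(f"need >= 3 cells to assign zonation, got {len(cell_ids)}")
    sub = nm.subset_cells(list(cell_ids))
    pp = module_score(sub, pp_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed).scores
    pc = module_score(sub, pc_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed).scores
    d = (pc - pp).to_numpy()
    lo, hi = np.quantile(d, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.full(len(d), "MZ", dtype=object)
    labels[d < lo] = "PP"
    labels[d > hi] = "PC"
    return pd.Series(labels, index=sub.cell_ids, name="zone")
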