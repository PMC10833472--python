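"""Aging DEG calling and downstream set algebra.

Per cell type, aged-vs-young genes are tested with a two-sided Wilcoxon
rank-sum (Mann-Whitney) test on normalized expression — exact when both groups
have at most 8 cells and no ties, normal approximation with tie correction
otherwise. Fold changes use the pseudocount-1-on-averaged-expm1 convention:

    avg_log2FC = log2(mean(expm1(x_aged)) + 1) - log2(mean(expm1(x_young)) + 1)
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_core import NormalizedMatrix

__all__ = [
    "bh_adjust",
    "avg_log2fc",
    "rank_sum_p",
    "wilcoxon_deg",
    "shared_degs",
    "overlap_modules",
    "signed_external_overlap",
    "MODULE_CLASSES",
]

SUBTYPES = ("PP", "MZ", "PC")

# 14 classes: 2 directions x 7 non-empty subsets of the three subtypes,
# in a fixed order so module ids are stable.
MODULE_CLASSES: list[tuple[str, frozenset]] = [
    (direction, frozenset(subset))
    for direction in ("up", "down")
    for size in (1, 2, 3)
    for subset in combinations(SUBTYPES, size)
]
MODULE_ID = {cls: i + 1 for i, cls in enumerate(MODULE_CLASSES)}


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("bh_adjust: NaN p-value in input")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("bh_adjust: p-values outside [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def avg_log2fc(x_target: np.ndarray, x_rest: np.ndarray) -> np.ndarray:
    """log2 fold change of group means of expm1-backtransformed values, pseudocount 1.

    Inputs are genes x cells blocks of normalized (log1p) expression.
    """
    mean_t = np.expm1(np.asarray(x_target, dtype=float)).mean(axis=-1)
    mean_r = np.expm1(np.asarray(x_rest, dtype=float)).mean(axis=-1)
    return np.log2(mean_t + 1.0) - np.log2(mean_r + 1.0)


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value.

    Exact null distribution when both samples have <= 8 observations and the
    pooled data is tie-free; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    return float(mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def wilcoxon_deg(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    min_pct: float = 0.1,
    lfc_prefilter: float = 0.25,
    lfc_sig: float = 0.25,
    padj_max: float = 0.05,
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Aged-vs-young differential expression for one cell type.

    Genes enter testing when detected in at least ``min_pct`` of either group
    and |avg_log2FC| >= ``lfc_prefilter``; BH adjustment runs over tested genes
    only. A record is flagged significant at p_adj <= ``padj_max`` and
    |avg_log2FC| >= ``lfc_sig``.
    """
    sub = meta[meta[cell_type_col] == cell_type]
    aged_ids = sub.loc[sub["group"] == "aged", "cell_id"].tolist()
    young_ids = sub.loc[sub["group"] == "young", "cell_id"].tolist()
    if len(aged_ids) < 3 or len(young_ids) < 3:
        raise ValueError(
            f"cell type {cell_type!r} needs >= 3 cells per group "
            f"(aged={len(aged_ids)}, young={len(young_ids)})"
        )
    x_aged = nm.subset_cells(aged_ids).dense()
    x_young = nm.subset_cells(young_ids).dense()

    pct_aged = (x_aged > 0).mean(axis=1)
    pct_young = (x_young > 0).mean(axis=1)
    lfc = avg_log2fc(x_aged, x_young)
    tested = ((pct_aged >= min_pct) | (pct_young >= min_pct)) & (
        np.abs(lfc) >= lfc_prefilter
    )
    idx = np.flatnonzero(tested)
    pvals = np.array([rank_sum_p(x_aged[i], x_young[i]) for i in idx])
    padj = bh_adjust(pvals) if idx.size else np.array([])

    genes = np.asarray(nm.gene_ids)
    table = pd.DataFrame(
        {
            "gene": genes[idx],
            "cell_type": cell_type,
            "avg_log2FC": lfc[idx],
            "p": pvals,
            "p_adj": padj,
            "pct_aged": pct_aged[idx],
            "pct_young": pct_young[idx],
        }
    )
    table["direction"] = np.where(table["avg_log2FC"] >= 0, "up", "down")
    table["significant"] = (table["p_adj"] <= padj_max) & (
        table["avg_log2FC"].abs() >= lfc_sig
    )
    return table.reset_index(drop=True)


def _significant_directions(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for name, table in tables.items():
        sig = table.loc[table["significant"].astype(bool)]
        frames.append(
            pd.DataFrame(
                {"gene": sig["gene"], "source": name, "direction": sig["direction"]}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["gene", "source", "direction"])
    return pd.concat(frames, ignore_index=True)


def shared_degs(tables: dict[str, pd.DataFrame], k_min: int = 3) -> pd.DataFrame:
    """Genes significant with the same direction in at least k_min cell types."""
    if len(tables) < k_min:
        raise ValueError(f"need >= {k_min} cell types, got {len(tables)}")
    sig = _significant_directions(tables)
    records = []
    for (gene, direction), grp in sig.groupby(["gene", "direction"], sort=True):
        types = sorted(grp["source"].unique())
        if len(types) >= k_min:
            records.append(
                {
                    "gene": gene,
                    "direction": direction,
                    "cell_types": ",".join(types),
                    "k": len(types),
                }
            )
    return pd.DataFrame(records, columns=["gene", "direction", "cell_types", "k"])


def overlap_modules(
    tables: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify DEGs by (direction, non-empty subtype subset) into 14 modules.

    ``tables`` maps each of the PP/MZ/PC subtypes to its DEG table. Genes with
    a consistent direction across the subtypes where they are significant get a
    module id; direction-discordant genes land in the second returned frame.
    """
    if set(tables) != set(SUBTYPES):
        raise ValueError(f"expected exactly the subtype tables {SUBTYPES}, got {sorted(tables)}")
    sig = _significant_directions(tables)
    assignments, discordant = [], []
    for gene, grp in sig.groupby("gene", sort=True):
        directions = set(grp["direction"])
        subtypes = frozenset(grp["source"])
        if len(directions) > 1:
            per = {
                s: d for s, d in zip(grp["source"], grp["direction"])
            }
            discordant.append(
                {
                    "gene": gene,
                    "subtypes": ",".join(s for s in SUBTYPES if s in subtypes),
                    "directions": ",".join(per[s] for s in SUBTYPES if s in per),
                }
            )
            continue
        direction = directions.pop()
        assignments.append(
            {
                "gene": gene,
                "direction": direction,
                "subtypes": ",".join(s for s in SUBTYPES if s in subtypes),
                "module_id": MODULE_ID[(direction, subtypes)],
            }
        )
    return (
        pd.DataFrame(assignments, columns=["gene", "direction", "subtypes", "module_id"]),
        pd.DataFrame(discordant, columns=["gene", "subtypes", "directions"]),
    )


def signed_external_overlap(
    deg_table: pd.DataFrame,
    external: pd.DataFrame,
    case_insensitive: bool = True,
) -> dict[str, set[str]]:
    """Intersect significant DEGs with a signed external gene list.

    ``external`` needs columns ``gene`` and ``sign`` (+/-, or up/down, or a
    signed number). Returns co_up / co_down / discordant sets of gene ids (as
    spelled in the DEG table).
    """

    def norm(g: str) -> str:
        return g.lower() if case_insensitive else g

    def parse_sign(s) -> int:
        text = str(s).strip().lower()
        if text in {"+", "up", "pos", "positive"}:
            return 1
        if text in {"-", "down", "neg", "negative"}:
            return -1
        return 1 if float(text) > 0 else -1

    ext_sign = {norm(g): parse_sign(s) for g, s in zip(external["gene"], external["sign"])}
    sig = deg_table.loc[deg_table["significant"].astype(bool)]
    co_up: set[str] = set()
    co_down: set[str] = set()
    disc: set[str] = set()
    for gene, direction in zip(sig["gene"], sig["direction"]):
        s = ext_sign.get(norm(gene))
        if s is None:
            continue
        deg_sign = 1 if direction == "up" else -1
        if deg_sign == 1 and s == 1:
            co_up.add(gene)
        elif deg_sign == -1 and s == -1:
            co_down.add(gene)
        else:
            disc.add(gene)
    if not (co_up or co_down or disc):
        warnings.warn("no overlap between DEG table and external signature", stacklevel=2)
    return {"co_up": co_up, "co_down": co_down, "discordant": disc}
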