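"""Ligand-receptor interaction scoring with a cell-type label permutation null.

The score of a pair for an ordered (sender, receiver) cell-type pair is the
arithmetic mean of the ligand's mean normalized expression over sender cells
and the receptor's mean over receiver cells, computed within one age group. A
null is built by shuffling cell-type labels among that group's cells; p-values
use the add-one estimator p = (1 + #{permuted >= observed}) / (1 + n_perm).
Records pass only when ligand and receptor are each detected in more than 10%
of their cluster's cells (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import NormalizedMatrix

__all__ = ["LRPair", "read_lr_pairs", "interaction_score", "permutation_test", "differential_network"]

MIN_EXPR_FRACTION = 0.10  # strict: "more than 10% of cells"


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str

    @property
    def pair_id(self) -> str:
        return f"{self.ligand}|{self.receptor}"


def read_lr_pairs(path) -> list[LRPair]:
    """Two-column TSV (ligand, receptor), with or without a header line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "ligand" not in cols or "receptor" not in cols:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["ligand", "receptor"])
    else:
        df.columns = cols
    return [LRPair(l, r) for l, r in zip(df["ligand"], df["receptor"])]


def _prepare(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    pairs: list[LRPair],
    group: str,
    cell_type_col: str,
):
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    usable, skipped = [], []
    for p in pairs:
        if p.ligand in gene_index and p.receptor in gene_index:
            usable.append(p)
        else:
            skipped.append(p)
    if skipped:
        warnings.warn(
            f"{len(skipped)} LR pairs reference genes absent from the matrix; skipped",
            stacklevel=3,
        )
    sub = meta[(meta["group"] == group) & meta[cell_type_col].notna()]
    cells = sub["cell_id"].tolist()
    if not cells:
        raise ValueError(f"no cells in group {group!r}")
    types = sorted(sub[cell_type_col].unique())
    if len(types) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 cell types")
    genes = sorted({g for p in usable for g in (p.ligand, p.receptor)})
    expr = nm.subset_genes(genes).subset_cells(cells).dense()
    gidx = {g: i for i, g in enumerate(genes)}
    labels = sub.set_index("cell_id").loc[cells, cell_type_col].to_numpy()
    type_codes = np.array([types.index(t) for t in labels])
    return usable, expr, gidx, types, type_codes


def _cluster_stats(expr: np.ndarray, type_codes: np.ndarray, n_types: int):
    """Per-(gene, cell type) mean expression and detection fraction."""
    counts = np.bincount(type_codes, minlength=n_types).astype(float)
    onehot = np.zeros((expr.shape[1], n_types))
    onehot[np.arange(expr.shape[1]), type_codes] = 1.0
    means = (expr @ onehot) / counts
    fracs = ((expr > 0).astype(float) @ onehot) / counts
    return means, fracs


def interaction_score(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    pairs: list[LRPair],
    group: str,
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Observed scores and expression-filter status for every (pair, sender, receiver)."""
    usable, expr, gidx, types, type_codes = _prepare(nm, meta, pairs, group, cell_type_col)
    means, fracs = _cluster_stats(expr, type_codes, len(types))
    rows = []
    for p in usable:
        li, ri = gidx[p.ligand], gidx[p.receptor]
        for si, sender in enumerate(types):
            for ti, receiver in enumerate(types):
                pct_l, pct_r = fracs[li, si], fracs[ri, ti]
                passes = (pct_l > MIN_EXPR_FRACTION) and (pct_r > MIN_EXPR_FRACTION)
                rows.append(
                    {
                        "pair_id": p.pair_id,
                        "ligand": p.ligand,
                        "receptor": p.receptor,
                        "sender": sender,
                        "receiver": receiver,
                        "group": group,
                        "score": 0.5 * (means[li, si] + means[ri, ti]),
                        "pct_ligand_sender": pct_l,
                        "pct_receptor_receiver": pct_r,
                        "expression_filter_pass": passes,
                    }
                )
    return pd.DataFrame(rows)


def permutation_test(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    pairs: list[LRPair],
    group: str,
    n_perm: int = 1000,
    seed: int = 0,
    p_max: float = 0.05,
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Label-permutation significance of every (pair, sender, receiver) record.

    Cell-type labels are shuffled among the group's cells (group membership is
    fixed); significant requires p <= ``p_max`` AND both detection fractions
    strictly above 10%.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives p-value resolution ~{1.0 / (n_perm + 1):.3f}",
            stacklevel=2,
        )
    usable, expr, gidx, types, type_codes = _prepare(nm, meta, pairs, group, cell_type_col)
    n_types = len(types)
    means, fracs = _cluster_stats(expr, type_codes, n_types)

    lig_rows = np.array([gidx[p.ligand] for p in usable])
    rec_rows = np.array([gidx[p.receptor] for p in usable])
    # observed[pair, sender, receiver]
    observed = 0.5 * (
        means[lig_rows][:, :, None] + means[rec_rows][:, None, :]
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    codes = type_codes.copy()
    for _ in range(n_perm):
        rng.shuffle(codes)
        perm_means, _ = _cluster_stats(expr, codes, n_types)
        perm_scores = 0.5 * (
            perm_means[lig_rows][:, :, None] + perm_means[rec_rows][:, None, :]
        )
        exceed += perm_scores >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for pi, p in enumerate(usable):
        li, ri = gidx[p.ligand], gidx[p.receptor]
        for si, sender in enumerate(types):
            for ti, receiver in enumerate(types):
                pct_l, pct_r = fracs[li, si], fracs[ri, ti]
                passes = (pct_l > MIN_EXPR_FRACTION) and (pct_r > MIN_EXPR_FRACTION)
                pv = float(pvals[pi, si, ti])
                rows.append(
                    {
                        "pair_id": p.pair_id,
                        "ligand": p.ligand,
                        "receptor": p.receptor,
                        "sender": sender,
                        "receiver": receiver,
                        "group": group,
                        "score": float(observed[pi, si, ti]),
                        "p": pv,
                        "pct_ligand_sender": pct_l,
                        "pct_receptor_receiver": pct_r,
                        "significant": bool(passes and pv <= p_max),
                        "reason": "" if passes else "expression filter",
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["n_perm"] = n_perm
    out.attrs["seed"] = seed
    return out


def differential_network(
    records_young: pd.DataFrame, records_aged: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Group-specific interactions and per-(sender, receiver) signed edge counts.

    An interaction is aged-specific when significant in aged and not in young
    (same pair/sender/receiver), and symmetrically for young-specific.
    Returns (diff_edges, aged_specific, young_specific).
    """
    key = ["pair_id", "sender", "receiver"]
    y = records_young.set_index(key)
    a = records_aged.set_index(key)
    if set(y.index) != set(a.index):
        raise ValueError("young and aged record universes differ (pairs / cell types)")
    y = y.loc[a.index]  # align
    a_sig = a["significant"].to_numpy(dtype=bool)
    y_sig = y["significant"].to_numpy(dtype=bool)
    aged_specific = a[a_sig & ~y_sig].reset_index()
    young_specific = y[y_sig & ~a_sig].reset_index()
    shared = a[a_sig & y_sig].reset_index()

    edges: dict[tuple[str, str], dict] = {}
    universe = a.reset_index()[["sender", "receiver"]].drop_duplicates()
    for sender, receiver in universe.itertuples(index=False):
        edges[(sender, receiver)] = {
            "sender": sender,
            "receiver": receiver,
            "n_aged_specific": 0,
            "n_young_specific": 0,
            "n_shared": 0,
        }
    for df, col in (
        (aged_specific, "n_aged_specific"),
        (young_specific, "n_young_specific"),
        (shared, "n_shared"),
    ):
        for sender, receiver in df[["sender", "receiver"]].itertuples(index=False):
            edges[(sender, receiver)][col] += 1
    diff = pd.DataFrame(edges.values()).sort_values(["sender", "receiver"]).reset_index(drop=True)
    diff["weight"] = diff["n_aged_specific"] - diff["n_young_specific"]
    return diff, aged_specific, young_specific
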