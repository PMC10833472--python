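"""Kappa similarity networks over term gene sets and hypergeometric enrichment."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .deg import bh_adjust

__all__ = ["TermSet", "kappa_similarity", "build_term_graph", "hypergeom_enrich"]


@dataclass
class TermSet:
    term_id: str
    genes: set
    description: str = ""

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no member genes")


def kappa_similarity(a: set, b: set, universe: set) -> float:
    """Cohen's kappa between two gene-membership vectors over a universe.

    From the 2x2 table (both / A only / B only / neither) with N = |universe|:
    p_o = (both + neither) / N, p_e from marginals, kappa = (p_o - p_e)/(1 - p_e).
    Identical full-universe sets (p_e = 1) return 1.
    """
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    a = set(a) & universe
    b = set(b) & universe
    n = len(universe)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    p_o = (both + neither) / n
    p_e = ((both + only_a) * (both + only_b) + (only_b + neither) * (only_a + neither)) / n**2
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def build_term_graph(
    terms: list[TermSet],
    threshold: float = 0.3,
    universe: set | None = None,
    node_metadata: dict[str, dict] | None = None,
) -> nx.Graph:
    """Undirected graph with an edge wherever pairwise kappa exceeds the threshold.

    The default universe is the union of member genes over all terms. Node
    attributes carry term size, description, and any user metadata (e.g.
    per-cell-type gene-hit proportions).
    """
    if len(terms) < 2:
        raise ValueError("need at least 2 terms to build a graph")
    if universe is None:
        universe = set().union(*(t.genes for t in terms))
    graph = nx.Graph()
    for t in terms:
        attrs = {"size": len(t.genes), "description": t.description}
        if node_metadata and t.term_id in node_metadata:
            attrs.update(node_metadata[t.term_id])
        graph.add_node(t.term_id, **attrs)
    for ta, tb in combinations(terms, 2):
        kappa = kappa_similarity(ta.genes, tb.genes, universe)
        if kappa > threshold:  # strict: "more than 0.3"
            graph.add_edge(ta.term_id, tb.term_id, kappa=kappa)
    return graph


def hypergeom_enrich(
    query: set,
    annotation: dict[str, set],
    universe: set,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of the query in each term.

    p = P(X >= k) with N = |universe|, K = |term ∩ universe|, n = |query|;
    BH across terms. Terms with K = 0 are skipped.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    n = len(query)
    big_n = len(universe)
    rows = []
    for term_id in sorted(annotation):
        members = set(annotation[term_id]) & universe
        big_k = len(members)
        if big_k == 0:
            continue
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {"term_id": term_id, "k": k, "K": big_k, "n": n, "N": big_n, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
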