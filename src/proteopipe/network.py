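"""Offline interaction-network subgraphing and hypergeometric enrichment.

Replaces live database queries with local files: protein-protein
association edges come from a STRING-style export (TSV with columns
``protein1``, ``protein2``, ``combined_score`` on the 0-1000 scale) and
term annotations from a GMT file. Significant-protein subnetworks are
the connected components of the induced subgraph; term enrichment uses
the upper hypergeometric tail against the quantified-protein universe
with BH FDR within each annotation category and top-20-by-FDR
reporting.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .selection import bh_adjust

__all__ = ["read_string_edges", "induced_subgraph", "read_gmt",
           "hypergeometric_enrichment"]

CATEGORIES = ("BP", "CC", "MF", "KEGG", "custom")
TOP_TERMS = 20


def read_string_edges(path: str | Path, min_score: int = 400) -> nx.Graph:
    """Load a STRING-export edge table into an undirected graph.

    Edges below ``min_score`` are dropped; duplicate undirected pairs
    keep the maximum score; self-loops are discarded. Malformed rows
    are reported with their one-based line number.
    """
    path = Path(path)
    edges = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["protein1", "protein2", "combined_score"]
    missing = [c for c in required if c not in edges.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    scores = pd.to_numeric(edges["combined_score"], errors="coerce")
    bad = scores.isna() | (scores < 0) | (scores > 1000) | (scores % 1 != 0)
    if bad.any():
        lineno = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: line {lineno}: combined_score must be an "
                         f"integer in [0, 1000], got {edges.loc[bad.idxmax(), 'combined_score']!r}")
    graph = nx.Graph()
    for p1, p2, score in zip(edges["protein1"], edges["protein2"], scores.astype(int)):
        if p1 == p2 or score < min_score:
            continue
        if graph.has_edge(p1, p2):
            graph[p1][p2]["combined_score"] = max(graph[p1][p2]["combined_score"], score)
        else:
            graph.add_edge(p1, p2, combined_score=score)
    return graph


def induced_subgraph(graph: nx.Graph, significant: Iterable[str],
                     min_component: int = 3) -> list[set[str]]:
    """Connected components of the subgraph induced on significant proteins.

    Components smaller than ``min_component`` are dropped; the rest are
    returned largest-first, ties broken by the lexicographically
    smallest member, so the ordering is deterministic.
    """
    nodes = set(significant) & set(graph.nodes)
    sub = graph.subgraph(nodes)
    comps = [set(c) for c in nx.connected_components(sub) if len(c) >= min_component]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Parse a GMT file into ``{term_id: {'name': str, 'genes': set}}``."""
    path = Path(path)
    terms: dict[str, dict] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT rows need term, "
                             "description and at least one gene")
        term_id, name, *genes = fields
        genes = [g for g in genes if g]
        terms[term_id] = {"name": name, "genes": set(genes)}
    return terms


def hypergeometric_enrichment(selected: Iterable[str],
                              annotations: Mapping[str, Mapping],
                              universe: Iterable[str],
                              categories: Mapping[str, str] | None = None,
                              top_n: int = TOP_TERMS) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with per-category BH FDR.

    ``annotations`` maps term id to ``{'name': ..., 'genes': set}`` (as
    returned by :func:`read_gmt`); term gene sets are intersected with
    the universe (by default, all quantified proteins). ``categories``
    optionally assigns each term to BP/CC/MF/KEGG; unknown terms fall
    into 'custom'. All terms are returned; ``top`` marks the ``top_n``
    lowest-q terms within each category (rank by q, ties by p then id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    M, N = len(universe), len(selected)
    rows = []
    for term_id, entry in annotations.items():
        genes = set(entry["genes"]) & universe
        if not genes:
            continue
        K = len(genes)
        overlap = len(genes & selected)
        # P(X >= overlap) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, N))
        rows.append({
            "term_id": term_id,
            "term_name": entry.get("name", term_id),
            "category": (categories or {}).get(term_id, "custom"),
            "universe_size": M,
            "term_size": K,
            "selected_size": N,
            "overlap": overlap,
            "p_value": min(p, 1.0),
        })
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "category",
                                        "universe_size", "term_size",
                                        "selected_size", "overlap", "p_value"])
    table["q_value"] = np.nan
    table["rank"] = pd.array([None] * len(table), dtype="Int64")
    table["top"] = False
    for cat, idx in table.groupby("category").groups.items():
        q = bh_adjust(table.loc[idx, "p_value"].to_numpy())
        table.loc[idx, "q_value"] = q
        order = table.loc[idx].sort_values(
            ["q_value", "p_value", "term_id"]).index
        table.loc[order, "rank"] = np.arange(1, len(order) + 1)
        table.loc[order[:top_n], "top"] = True
    return table.sort_values(["category", "rank"]).reset_index(drop=True)
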