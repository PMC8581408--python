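"""Hypergeometric over-representation analysis (ORA) of signed gene pools.

For a query list (e.g. the positively correlated genes of one pool) and a
gene-set collection, each set is tested with the upper-tail hypergeometric
P(X >= k) where k is the observed overlap, K the set size after intersection
with the universe, n the query size and N the universe size; BH correction is
applied across tested sets. The universe defaults to the genes actually
tested in the corresponding model. Redundant sets are pruned greedily by
member-overlap (Jaccard) similarity, and the surviving top sets can be
exported as a bipartite gene-concept network annotated with pool membership.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Optional, Set

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .gmt import GeneSetCollection
from .nb_glm import bh_adjust
from .pooling import GenePool

ORA_COLUMNS = ["set_name", "k", "K", "n", "N", "pvalue", "padj", "enriched", "genes"]


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every eligible set against the query.

    Set members are intersected with the universe before testing; sets whose
    intersected size falls outside [min_size, max_size] are skipped. Raises if
    the query is not a subset of the universe; an empty query yields an empty
    table with a warning.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query contains genes outside the universe, e.g. {extra}")
    if not query:
        warnings.warn("empty query: returning an empty enrichment table")
        return pd.DataFrame(columns=ORA_COLUMNS)
    n, big_n = len(query), len(universe)
    rows = []
    for name, members in collection.sets.items():
        inter = members & universe
        if not (min_size <= len(inter) <= max_size):
            continue
        overlap = inter & query
        k, big_k = len(overlap), len(inter)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {"set_name": name, "k": k, "K": big_k, "n": n, "N": big_n,
             "pvalue": min(p, 1.0), "genes": ",".join(sorted(overlap))}
        )
    table = pd.DataFrame(rows, columns=[c for c in ORA_COLUMNS if c not in ("padj", "enriched")])
    if table.empty:
        table["padj"] = []
        table["enriched"] = []
        return table[ORA_COLUMNS]
    table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    table["enriched"] = table["padj"] < alpha
    table = table.sort_values(["padj", "pvalue", "set_name"]).reset_index(drop=True)
    return table[ORA_COLUMNS]


def prune_redundant(
    table: pd.DataFrame,
    collection: GeneSetCollection,
    universe: Iterable[str],
    jaccard_threshold: float = 0.7,
) -> pd.DataFrame:
    """Greedy redundancy pruning on universe-intersected set members.

    Walking the table from most to least significant (ties broken by name), a
    set is kept unless its Jaccard similarity with an already-kept set reaches
    the threshold. With threshold 1.0 only exact duplicates are removed.
    """
    universe = set(universe)
    ordered = table.sort_values(["padj", "pvalue", "set_name"])
    kept_names = []
    kept_members = []
    for _, row in ordered.iterrows():
        members = collection.sets[row["set_name"]] & universe
        redundant = False
        for other in kept_members:
            union = members | other
            if union and len(members & other) / len(union) >= jaccard_threshold:
                redundant = True
                break
        if not redundant:
            kept_names.append(row["set_name"])
            kept_members.append(members)
    return ordered[ordered["set_name"].isin(kept_names)].reset_index(drop=True)


def concept_network(
    table: pd.DataFrame,
    pools: Dict[str, GenePool],
    top_k: int = 5,
) -> nx.Graph:
    """Bipartite set-gene graph for the ``top_k`` most significant sets.

    Gene nodes carry a ``pools`` attribute: the sorted labels of the pools in
    which that gene is a member, enabling the pie-chart style annotation of
    shared versus metric- or timepoint-specific genes.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    graph = nx.Graph()
    top = table.sort_values(["padj", "pvalue", "set_name"]).head(top_k)
    for _, row in top.iterrows():
        set_node = row["set_name"]
        graph.add_node(set_node, bipartite=0, kind="set", padj=float(row["padj"]))
        genes = [g for g in str(row["genes"]).split(",") if g]
        for gene in genes:
            if gene not in graph:
                membership = sorted(lab for lab, pool in pools.items() if gene in pool.members)
                graph.add_node(gene, bipartite=1, kind="gene", pools=membership)
            graph.add_edge(set_node, gene)
    return graph


def network_edge_list(graph: nx.Graph) -> pd.DataFrame:
    """Edge-list export: set, gene, comma-joined pool membership."""
    rows = []
    for u, v in sorted(graph.edges()):
        set_node, gene = (u, v) if graph.nodes[u].get("kind") == "set" else (v, u)
        rows.append(
            {"set_name": set_node, "gene": gene,
             "pools": ",".join(graph.nodes[gene].get("pools", []))}
        )
    return pd.DataFrame(rows, columns=["set_name", "gene", "pools"])
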