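"""Signed gene pools and exclusive intersection (UpSet) accounting.

Significant genes from the linear- and exponential-form models of one metric
at one timepoint are merged via union into a pool (4 pools total: CE/MBA x
6h/24h). Each pooled gene carries a sign (+/- for positive/negative metric
coefficient) and its best adjusted p across the two contributing models.
UpSet-style accounting then partitions the union of direction-filtered pool
members into exclusive subset bins.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenePool:
    """Union of significant genes from a linear/exponential model pair."""

    label: str
    members: Set[str]
    sign: Dict[str, str]  # gene -> "+" | "-"
    best_padj: Dict[str, float]

    def direction(self, direction: str) -> Set[str]:
        if direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")
        return {g for g in self.members if self.sign[g] == direction}


def merge_pool(fit_linear: pd.DataFrame, fit_exp: pd.DataFrame, alpha: float, label: str = "") -> GenePool:
    """Union the significant genes of the two dose-form models.

    Sign and best adjusted p come from whichever model is more significant for
    that gene; sign conflicts between the two forms are resolved the same way
    and logged for audit.
    """
    if set(fit_linear.index) != set(fit_exp.index):
        raise ValueError("fit tables cover different gene universes")
    members: Set[str] = set()
    sign: Dict[str, str] = {}
    best: Dict[str, float] = {}
    n_conflicts = 0
    for gene in fit_linear.index:
        rows = []
        for tab in (fit_linear, fit_exp):
            padj = tab.at[gene, "padj"]
            if pd.notna(padj) and padj < alpha:
                rows.append((float(padj), float(tab.at[gene, "coef"])))
        if not rows:
            continue
        rows.sort()
        members.add(gene)
        best[gene] = rows[0][0]
        sign[gene] = "+" if rows[0][1] >= 0 else "-"
        if len(rows) == 2 and (rows[0][1] >= 0) != (rows[1][1] >= 0):
            n_conflicts += 1
            logger.warning("gene %s: linear/exponential sign conflict; using the more significant model", gene)
    if n_conflicts:
        logger.info("pool %s: %d sign conflicts resolved by smaller padj", label or "?", n_conflicts)
    return GenePool(label=label, members=members, sign=sign, best_padj=best)


def overlap_fraction(set1: Iterable[str], set2: Iterable[str]) -> float:
    """Jaccard fraction |A & B| / |A | B|; two empty sets count as identical."""
    s1, s2 = set(set1), set(set2)
    union = s1 | s2
    if not union:
        warnings.warn("overlap of two empty sets defined as 1")
        return 1.0
    return len(s1 & s2) / len(union)


def upset_intersections(pools: List[GenePool], direction: str) -> pd.DataFrame:
    """Exclusive subset bins over the direction-filtered union of the pools.

    Every gene lands in exactly one bin — the set of pools that contain it —
    so bin counts sum to the union size. Rows ordered by count descending,
    then by subset label.
    """
    labels = [p.label for p in pools]
    if len(set(labels)) != len(labels):
        raise ValueError("pool labels must be distinct")
    filtered = {p.label: p.direction(direction) for p in pools}
    union: Set[str] = set().union(*filtered.values()) if filtered else set()
    bins: Dict[Tuple[str, ...], List[str]] = {}
    for gene in union:
        key = tuple(lab for lab in labels if gene in filtered[lab])
        bins.setdefault(key, []).append(gene)
    rows = [
        {"subset": "&".join(key), "degree": len(key), "exclusive_count": len(genes), "genes": ",".join(sorted(genes))}
        for key, genes in bins.items()
    ]
    df = pd.DataFrame(rows, columns=["subset", "degree", "exclusive_count", "genes"])
    if not df.empty:
        df = df.sort_values(["exclusive_count", "subset"], ascending=[False, True]).reset_index(drop=True)
    return df


def build_pools(tables: Dict[str, pd.DataFrame], alpha: float = 0.05) -> Dict[str, GenePool]:
    """Assemble the 4 pools (metric x timepoint) from the 8 fit tables.

    Pools whose linear or exponential member table is missing (skipped model)
    are omitted with a log message.
    """
    pools: Dict[str, GenePool] = {}
    for metric, tp in itertools.product(("ce", "mba"), ("6h", "24h")):
        lin, exp = f"{metric}_linear_{tp}", f"{metric}_exponential_{tp}"
        if lin not in tables or exp not in tables:
            logger.error("pool %s_%s omitted: contributing model missing", metric, tp)
            continue
        label = f"{metric}_{tp}"
        pools[label] = merge_pool(tables[lin], tables[exp], alpha, label=label)
    return pools


def pools_to_frame(pools: Dict[str, GenePool]) -> pd.DataFrame:
    """Long-format membership table (gene, pool, sign, best_padj)."""
    rows = [
        {"gene": g, "pool": pool.label, "sign": pool.sign[g], "best_padj": pool.best_padj[g]}
        for pool in pools.values()
        for g in sorted(pool.members)
    ]
    return pd.DataFrame(rows, columns=["gene", "pool", "sign", "best_padj"])
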