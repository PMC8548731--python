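"""Cis neighbor-gene pairing and gene-set over-representation.

Each differentially expressed lncRNA is paired with its nearest
protein-coding genes on either side (up to five upstream and five downstream
by closest-edge distance, chromosome orientation).  Pairs survive filtering
when the coding gene is differentially expressed, the lncRNA is
differentially expressed, and the lncRNA carries at least one differential
m6A peak; surviving pairs are labelled positive (same expression sign) or
retrograde (opposite signs).  Query gene lists are scored against
user-supplied GMT gene sets with a hypergeometric over-representation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import Gene, GenomeAnnotation
from .merip_peaks import DiffPeakRecord, bh_adjust

logger = logging.getLogger(__name__)

PADJ_THRESHOLD = 0.05
PEAK_FDR_THRESHOLD = 0.05
DEFAULT_K = 5


@dataclass
class NeighborPair:
    lnc_gene_id: str
    coding_gene_id: str
    side: str        # upstream / downstream
    rank: int        # 1..k by proximity within the side
    distance: int    # closest-edge gap, 0 when overlapping
    lnc_log2fc: float = float("nan")
    coding_log2fc: float = float("nan")
    concordance: str = "NA"


def _side_and_distance(lnc: Gene, g: Gene) -> tuple[str, int]:
    if g.end <= lnc.start:
        return "upstream", lnc.start - g.end
    if g.start >= lnc.end:
        return "downstream", g.start - lnc.end
    # overlapping: side of its start coordinate, distance 0
    return ("upstream" if g.start < lnc.start else "downstream"), 0


def find_neighbors(lnc_gene_id: str, annotation: GenomeAnnotation,
                   k: int = DEFAULT_K,
                   lnc_strand_aware: bool = False) -> list[NeighborPair]:
    """Nearest protein-coding genes on each side of a lncRNA.

    Sides follow chromosome orientation (upstream = lower coordinates); with
    ``lnc_strand_aware`` they follow the lncRNA's own strand instead.  Ranks
    order by closest-edge distance, ties broken by smaller gene start; fewer
    than k neighbors are returned near chromosome ends.
    """
    if lnc_gene_id not in annotation.genes:
        raise KeyError(f"gene {lnc_gene_id} not in annotation")
    lnc = annotation.genes[lnc_gene_id]
    buckets: dict[str, list[tuple[int, int, str]]] = {"upstream": [],
                                                      "downstream": []}
    for g in annotation.coding_genes():
        if g.chrom != lnc.chrom or g.gene_id == lnc.gene_id:
            continue
        side, dist = _side_and_distance(lnc, g)
        buckets[side].append((dist, g.start, g.gene_id))
    swap = lnc_strand_aware and lnc.strand == "-"
    pairs = []
    for side, cands in buckets.items():
        label = {"upstream": "downstream", "downstream": "upstream"}[side] \
            if swap else side
        for rank, (dist, _, gid) in enumerate(sorted(cands)[:k], start=1):
            pairs.append(NeighborPair(lnc_gene_id, gid, label, rank, dist))
    return pairs


def find_all_neighbors(lnc_gene_ids: Iterable[str],
                       annotation: GenomeAnnotation,
                       k: int = DEFAULT_K) -> list[NeighborPair]:
    out = []
    for gid in sorted(lnc_gene_ids):
        out.extend(find_neighbors(gid, annotation, k=k))
    return out


def pair_filter(pairs: Sequence[NeighborPair], de_results: pd.DataFrame,
                diff_peaks: Sequence[DiffPeakRecord],
                padj_threshold: float = PADJ_THRESHOLD,
                peak_fdr_threshold: float = PEAK_FDR_THRESHOLD
                ) -> list[NeighborPair]:
    """Keep dual-significant pairs and classify their concordance.

    A pair survives when the coding gene is DE (padj <= threshold), the
    lncRNA is DE, and the lncRNA owns >= 1 differential peak at
    FDR <= threshold.  Concordance is positive for equal expression-change
    signs, retrograde for opposite.
    """
    de = de_results.set_index("gene_id") if "gene_id" in de_results.columns \
        else de_results
    meth_ok = {d.peak.gene_id for d in diff_peaks
               if d.fdr <= peak_fdr_threshold}

    def de_sig(gid: str) -> bool:
        return (gid in de.index and pd.notna(de.at[gid, "padj"])
                and de.at[gid, "padj"] <= padj_threshold)

    kept = []
    for p in pairs:
        if not (de_sig(p.coding_gene_id) and de_sig(p.lnc_gene_id)
                and p.lnc_gene_id in meth_ok):
            continue
        l_fc = float(de.at[p.lnc_gene_id, "log2FoldChange"])
        c_fc = float(de.at[p.coding_gene_id, "log2FoldChange"])
        conc = "positive" if l_fc * c_fc > 0 else \
            "retrograde" if l_fc * c_fc < 0 else "NA"
        kept.append(NeighborPair(p.lnc_gene_id, p.coding_gene_id, p.side,
                                 p.rank, p.distance, l_fc, c_fc, conc))
    logger.info("pair_filter: %d/%d pairs kept", len(kept), len(pairs))
    return kept


def pairs_to_dataframe(pairs: Sequence[NeighborPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "lnc": p.lnc_gene_id, "coding": p.coding_gene_id, "side": p.side,
        "rank": p.rank, "distance": p.distance,
        "lnc_log2fc": p.lnc_log2fc, "coding_log2fc": p.coding_log2fc,
        "concordance": p.concordance,
    } for p in pairs])


# --------------------------------------------------------------------------
# Gene-set over-representation
# --------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}")


def read_gmt(path: str, universe: Iterable[str] | None = None
             ) -> GeneSetCollection:
    """GMT reader: one set per line (name, description, members...)."""
    sets, desc = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[fields[0]] = set(fields[2:])
            desc[fields[0]] = fields[1]
    return GeneSetCollection(sets, desc,
                             set(universe) if universe is not None else set())


def ora(query_genes: Iterable[str], collection: GeneSetCollection
        ) -> pd.DataFrame:
    """Hypergeometric over-representation of a query in each gene set.

    p = P(X >= overlap) with population N = |universe|, K = |set|,
    n = |query|; BH across sets; fold = (overlap/n) / (K/N).  Every query
    gene must belong to the universe.
    """
    query = set(query_genes)
    stray = query - collection.universe
    if stray:
        raise ValueError(
            f"query genes outside the universe: {sorted(stray)[:10]}")
    N, n = len(collection.universe), len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        fold = (overlap / n) / (K / N) if n and K else float("nan")
        rows.append({"set": name,
                     "description": collection.descriptions.get(name, ""),
                     "overlap": overlap, "set_size": K, "query_size": n,
                     "universe_size": N, "fold": fold, "pvalue": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["qvalue"] = bh_adjust(df.pvalue.to_numpy())
        df = df.sort_values(["pvalue", "set"]).reset_index(drop=True)
    return df
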