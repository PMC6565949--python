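"""Genomic context and gene-set layers.

Three independent reports: genes within a fixed window of a lncRNA locus
(candidate cis-regulated targets), hypergeometric over-representation of
gene sets in a query list, and 2–3-way set-overlap (Venn) tables against
external disease-gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.chrom}:{self.start}-{self.end})")

    @classmethod
    def from_1based_closed(cls, chrom: str, start: int, end: int, strand: str = ".") -> "GenomicInterval":
        """Convert coordinates printed in the 1-based closed convention."""
        return cls(chrom, start - 1, end, strand)


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Base pairs separating two intervals; 0 when they touch or overlap.

    ``None`` for intervals on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(a.start - b.end, b.start - a.end, 0)


def cis_targets(
    lncrna: GenomicInterval, genes: pd.DataFrame, window: int = 10_000
) -> pd.DataFrame:
    """Genes on the lncRNA's chromosome within ``window`` bp of its locus.

    The window is applied symmetrically on both flanks regardless of strand,
    and the boundary is inclusive (a gap of exactly ``window`` bp counts).
    ``genes`` needs columns transcript_id/chrom/start/end (0-based,
    half-open).  Distance is 0 for any overlap, otherwise the gap length.
    Result is sorted by distance then id; empty when nothing is in range.
    """
    same = genes.loc[genes["chrom"] == lncrna.chrom]
    if same.empty:
        return pd.DataFrame(columns=["transcript_id", "chrom", "start", "end", "distance"])
    gap = np.maximum(
        np.maximum(lncrna.start - same["end"], same["start"] - lncrna.end), 0
    )
    hits = same.loc[gap <= window, ["transcript_id", "chrom", "start", "end"]].copy()
    hits["distance"] = gap[gap <= window].astype(int)
    return hits.sort_values(["distance", "transcript_id"]).reset_index(drop=True)


@dataclass
class GeneSetCollection:
    """Named gene sets over a stated universe.

    Sets are clipped to the universe on construction; names must be unique
    (guaranteed by the dict container).
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        self.universe = set(self.universe)
        if not self.universe:
            raise ValueError("universe is empty")
        self.sets = {name: set(s) & self.universe for name, s in self.sets.items()}


def gene_set_enrichment(query: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set in the query.

    With universe size N, set size K, query size n and k hits, the p-value is
    ``P(X >= k)`` for X hypergeometric(N, K, n).  Query ids outside the
    universe are dropped (count logged).  Results are sorted by p ascending
    with a BH column; ``enriched`` applies the raw p < 0.05 threshold.
    """
    query = set(query)
    dropped = query - collection.universe
    if dropped:
        log.info("dropping %d query ids outside the universe", len(dropped))
    query &= collection.universe
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(query & members)
        # survival function at k-1 gives P(X >= k); k=0 → p = 1 exactly
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p_hyper": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_hyper"])
    if len(result):
        result["p_adj"] = multipletests(result["p_hyper"], method="fdr_bh")[1]
        result["enriched"] = result["p_hyper"] < 0.05
        result = result.sort_values(["p_hyper", "set_name"]).reset_index(drop=True)
    else:
        result["p_adj"] = []
        result["enriched"] = []
    return result


def _normalise(ids) -> set[str]:
    return {str(g).strip().casefold() for g in ids if str(g).strip()}


def set_overlap(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Every Venn region of 2–3 named sets with its count and members.

    Ids are normalised (case-folded, whitespace-trimmed) before comparison.
    Regions are exclusive — each element of the union lands in exactly one —
    so the region counts sum to |union|.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("set_overlap reports 2- or 3-way diagrams only")
    names = list(sets)
    norm = {name: _normalise(sets[name]) for name in names}
    union = set().union(*norm.values())
    rows = []
    for membership in product([True, False], repeat=len(names)):
        if not any(membership):
            continue
        inside = [n for n, m in zip(names, membership) if m]
        outside = [n for n, m in zip(names, membership) if not m]
        region = set(union)
        for n in inside:
            region &= norm[n]
        for n in outside:
            region -= norm[n]
        rows.append(
            {
                "region": "&".join(inside),
                "count": len(region),
                "members": ",".join(sorted(region)),
            }
        )
    return pd.DataFrame(rows, columns=["region", "count", "members"])
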