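"""Overlapping gene pairs and poly(A) sites at convergent conjunctions.

Overlap is computed on annotated (unextended) gene spans. Opposite-
strand pairs are convergent when their 3' ends face each other and
divergent when their 5' ends do. Convergent pairs with a 350-1000 nt
overlap are the conjunction set: each gene end is checked for a
supporting ("normal") 3'UTR PAC, and PACs inside the overlap are the
"opposite" PACs of the partner gene, split by whether the partner
hosts them in its 3'UTR or in a non-3'UTR region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation import GeneModel
from .classification import N3PAS_CATEGORIES, PacCall

MIN_CONJUNCTION_OVERLAP = 350
MAX_CONJUNCTION_OVERLAP = 1000

ORIENTATIONS = ("convergent", "divergent", "same")


@dataclass(frozen=True)
class OverlapPair:
    gene_a: str
    gene_b: str
    chrom: str
    orientation: str
    overlap_start: int
    overlap_end: int

    @property
    def overlap_len(self) -> int:
        return self.overlap_end - self.overlap_start + 1


def _orientation(a: GeneModel, b: GeneModel) -> str:
    if a.strand == b.strand:
        return "same"
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    # 3' ends face each other when the + gene lies to the left
    if (plus.gene_start, plus.gene_end) <= (minus.gene_start, minus.gene_end):
        return "convergent"
    return "divergent"


def find_overlap_pairs(genes: Iterable[GeneModel]) -> list[OverlapPair]:
    """Every unordered gene pair whose annotated spans intersect."""
    pairs: list[OverlapPair] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: (g.gene_start, g.gene_id))
        for i, a in enumerate(gs):
            for b in gs[i + 1 :]:
                if b.gene_start > a.gene_end:
                    break
                lo = max(a.gene_start, b.gene_start)
                hi = min(a.gene_end, b.gene_end)
                if lo > hi:
                    continue
                pairs.append(
                    OverlapPair(
                        gene_a=a.gene_id,
                        gene_b=b.gene_id,
                        chrom=chrom,
                        orientation=_orientation(a, b),
                        overlap_start=lo,
                        overlap_end=hi,
                    )
                )
    return pairs


def orientation_census(pairs: Sequence[OverlapPair]) -> pd.DataFrame:
    counts = {o: 0 for o in ORIENTATIONS}
    for p in pairs:
        counts[p.orientation] += 1
    df = pd.DataFrame(
        {"n_pairs": [counts[o] for o in ORIENTATIONS]}, index=ORIENTATIONS
    )
    df.index.name = "orientation"
    return df


def select_conjunction_pairs(
    pairs: Sequence[OverlapPair],
    min_len: int = MIN_CONJUNCTION_OVERLAP,
    max_len: int = MAX_CONJUNCTION_OVERLAP,
) -> list[OverlapPair]:
    """Convergent pairs whose overlap length falls in [min_len, max_len]."""
    return [
        p
        for p in pairs
        if p.orientation == "convergent" and min_len <= p.overlap_len <= max_len
    ]


def tally_conjunction_pacs(
    pairs: Sequence[OverlapPair], calls: Sequence[PacCall]
) -> dict:
    """Normal vs opposite PAC tallies over the selected pairs.

    A gene end is "normal"-supported when a 3'UTR call hosted by that
    gene exists. An "opposite" PAC is a call whose representative site
    lies inside the pair's overlap and that is hosted by one of the
    two genes in its sense orientation; relative to the partner gene it
    runs on the opposite strand. Opposite PACs split into those the
    host carries in its 3'UTR and those it carries as non-3'UTR sites
    (the conjunction reaching the host's coding region).
    """
    hosts_3utr: set[str] = set()
    by_host: dict[str, list[PacCall]] = {}
    for c in calls:
        if c.host_gene is None:
            continue
        by_host.setdefault(c.host_gene, []).append(c)
        if c.category == "ThreeUTR":
            hosts_3utr.add(c.host_gene)
    n_normal = 0
    opposite_calls: dict[str, str] = {}  # pac_id -> category class
    rows = []
    for p in pairs:
        normal_a = p.gene_a in hosts_3utr
        normal_b = p.gene_b in hosts_3utr
        n_normal += int(normal_a) + int(normal_b)
        opp_here = {"ThreeUTR": 0, "n3PAS": 0}
        for host in (p.gene_a, p.gene_b):
            for c in by_host.get(host, []):
                if not (p.overlap_start <= c.pac.rep_pos <= p.overlap_end):
                    continue
                if c.category == "ThreeUTR":
                    kind = "ThreeUTR"
                elif c.category in N3PAS_CATEGORIES:
                    kind = "n3PAS"
                else:
                    continue
                opposite_calls[c.pac.pac_id] = kind
                opp_here[kind] += 1
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "overlap_len": p.overlap_len,
                "normal_a": normal_a,
                "normal_b": normal_b,
                "opposite_3utr": opp_here["ThreeUTR"],
                "opposite_n3pas": opp_here["n3PAS"],
            }
        )
    n_opp_3utr = sum(1 for k in opposite_calls.values() if k == "ThreeUTR")
    n_opp_n3 = sum(1 for k in opposite_calls.values() if k == "n3PAS")
    return {
        "n_pairs": len(pairs),
        "n_gene_ends": 2 * len(pairs),
        "normal_supported_ends": n_normal,
        "opposite_pacs": n_opp_3utr + n_opp_n3,
        "opposite_3utr": n_opp_3utr,
        "opposite_n3pas": n_opp_n3,
        "per_pair": pd.DataFrame(rows),
    }
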