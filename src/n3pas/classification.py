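"""Six-way genic classification of poly(A) site clusters.

A PAC is placed by its representative site. If that position falls in
a same-strand gene's longest transcript (or its 120 nt 3' extension)
the segment type decides the category; otherwise an opposite-strand
extended gene span makes it antisense, and anything else is
intergenic. Sense beats antisense beats intergenic.

The 400 nt rule then rescues mis-annotated 5'UTR calls that are really
read-through 3'UTR sites of the nearest upstream same-strand gene.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel
from .extraction import PAC

CATEGORIES = (
    "FiveUTR",
    "CdsExon",
    "CdsIntron",
    "ThreeUTR",
    "Intergenic",
    "Antisense",
)
N3PAS_CATEGORIES = frozenset({"FiveUTR", "CdsExon", "CdsIntron"})
SENSE_CATEGORIES = frozenset({"FiveUTR", "CdsExon", "CdsIntron", "ThreeUTR"})

# host tie-break between overlapping same-strand genes: most 3' wins
_CATEGORY_RANK = {"ThreeUTR": 3, "CdsIntron": 2, "CdsExon": 1, "FiveUTR": 0}

DEFAULT_RECLASS_CUTOFF = 400


@dataclass(frozen=True)
class PacCall:
    """A classified PAC."""

    pac: PAC
    category: str
    host_gene: str | None
    subtype: str | None = None  # exon|intron|extension for UTR categories
    reclassified: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "Intergenic") != (self.host_gene is None):
            raise ValueError("host_gene must be None iff Intergenic")


def _classify_in_transcript(gene: GeneModel, pos: int) -> tuple[str, str] | None:
    """Category and subtype of a position against the longest transcript
    (including the 120 nt extension zone), or None when outside."""
    tx = gene.longest_tx
    term = tx.three_prime_end
    if gene.strand == "+":
        if term < pos <= gene.extended_end:
            return "ThreeUTR", "extension"
    else:
        if gene.extended_end <= pos < term:
            return "ThreeUTR", "extension"
    if not (tx.tx_start <= pos <= tx.tx_end):
        return None
    for s, e in tx.five_utr_segments:
        if s <= pos <= e:
            return "FiveUTR", "exon"
    for s, e in tx.three_utr_segments:
        if s <= pos <= e:
            return "ThreeUTR", "exon"
    for s, e in tx.cds_exon_segments:
        if s <= pos <= e:
            return "CdsExon", "exon"
    for s, e in tx.intron_segments:
        if s <= pos <= e:
            if not tx.cds_exon_segments:
                return "CdsIntron", "intron"
            cds_lo = min(s2 for s2, _ in tx.cds_exon_segments)
            cds_hi = max(e2 for _, e2 in tx.cds_exon_segments)
            if pos < cds_lo:
                sub = "FiveUTR" if gene.strand == "+" else "ThreeUTR"
            elif pos > cds_hi:
                sub = "ThreeUTR" if gene.strand == "+" else "FiveUTR"
            else:
                sub = "CdsIntron"
            if sub == "CdsIntron":
                return "CdsIntron", "intron"
            return sub, "intron"
    return None


class AnnotationIndex:
    """Interval index over extended gene spans for fast position lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        # per (chrom, strand): sorted transcript 3' termini for the
        # upstream-gene search used by the 400 nt reclassification
        self._termini: dict[tuple[str, str], tuple[list[int], list[GeneModel]]] = {}
        for g in self.genes:
            s, e = g.extended_span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(s, e + 1, g)
        term_acc: dict[tuple[str, str], list[tuple[int, GeneModel]]] = {}
        for g in self.genes:
            term_acc.setdefault((g.chrom, g.strand), []).append(
                (g.longest_tx.three_prime_end, g)
            )
        for key, pairs in term_acc.items():
            pairs.sort(key=lambda p: (p[0], p[1].gene_id))
            self._termini[key] = ([p for p, _ in pairs], [g for _, g in pairs])

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda g: g.gene_id)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees

    def locate(self, chrom: str, strand: str, pos: int) -> tuple[str, str | None, str | None]:
        """(category, host_gene, subtype) of a strand-aware position."""
        if not self._trees:
            raise ValueError("annotation index is empty")
        if chrom not in self._trees:
            raise KeyError(f"chromosome {chrom!r} absent from annotation")
        hits = self.overlapping(chrom, pos)
        sense: list[tuple[int, int, str, str, GeneModel]] = []
        antisense: list[GeneModel] = []
        for g in hits:
            if g.strand == strand:
                res = _classify_in_transcript(g, pos)
                if res is not None:
                    cat, sub = res
                    dist_3p = abs(pos - g.longest_tx.three_prime_end)
                    sense.append((_CATEGORY_RANK[cat], -dist_3p, cat, sub, g))
            else:
                antisense.append(g)
        if sense:
            sense.sort(key=lambda t: (-t[0], -t[1], t[4].gene_id))
            _, _, cat, sub, g = sense[0]
            return cat, g.gene_id, sub
        if antisense:
            host = min(
                antisense,
                key=lambda g: (abs(pos - g.longest_tx.three_prime_end), g.gene_id),
            )
            return "Antisense", host.gene_id, None
        return "Intergenic", None, None

    def upstream_terminus(
        self, chrom: str, strand: str, pos: int, exclude: str | None = None
    ) -> tuple[GeneModel, int] | None:
        """Nearest same-strand gene whose 3' terminus lies strictly 5'
        of ``pos``; returns (gene, distance terminus -> pos)."""
        key = (chrom, strand)
        if key not in self._termini:
            return None
        positions, genes = self._termini[key]
        if strand == "+":
            i = bisect.bisect_left(positions, pos) - 1
            step = -1
        else:
            i = bisect.bisect_right(positions, pos)
            step = 1
        while 0 <= i < len(positions):
            g = genes[i]
            if g.gene_id != exclude:
                dist = pos - positions[i] if strand == "+" else positions[i] - pos
                return g, dist
            i += step
        return None


def classify_pac(pac: PAC, index: AnnotationIndex) -> PacCall:
    """Classify one PAC by its representative site position."""
    cat, host, sub = index.locate(pac.chrom, pac.strand, pac.rep_pos)
    return PacCall(pac=pac, category=cat, host_gene=host, subtype=sub)


def classify_pacs(pacs: Sequence[PAC], index: AnnotationIndex) -> list[PacCall]:
    return [classify_pac(p, index) for p in pacs]


def reclassify_5utr(
    calls: Sequence[PacCall],
    index: AnnotationIndex,
    cutoff: int = DEFAULT_RECLASS_CUTOFF,
) -> list[PacCall]:
    """Relabel 5'UTR calls that sit within ``cutoff`` nt downstream of
    the nearest upstream same-strand gene's 3' terminus as that gene's
    3'UTR calls (read-through mis-annotations). Idempotent; all other
    calls pass through unchanged.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    out: list[PacCall] = []
    for call in calls:
        if call.category != "FiveUTR" or call.reclassified:
            out.append(call)
            continue
        pac = call.pac
        found = index.upstream_terminus(
            pac.chrom, pac.strand, pac.rep_pos, exclude=call.host_gene
        )
        if found is not None:
            gene, dist = found
            if 0 < dist <= cutoff:
                out.append(
                    replace(
                        call,
                        category="ThreeUTR",
                        host_gene=gene.gene_id,
                        reclassified=True,
                    )
                )
                continue
        out.append(call)
    return out


def tally_categories(calls: Sequence[PacCall]) -> pd.DataFrame:
    """Per-category PAC and tag counts, plus the n3PAS aggregate row."""
    rows = {}
    for cat in CATEGORIES:
        sub = [c for c in calls if c.category == cat]
        rows[cat] = (len(sub), sum(c.pac.total_tags for c in sub))
    n3 = [c for c in calls if c.category in N3PAS_CATEGORIES]
    rows["n3PAS"] = (len(n3), sum(c.pac.total_tags for c in n3))
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_pacs", "n_tags"]
    )
    df.index.name = "category"
    return df
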