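"""Host-gene architecture labels and their relation to PAC content.

Genes are labeled for atypical 5'UTRs (spliced / ambiguous / extreme
short, with precedence spliced > ambiguous > extreme short), for long
introns (> 800 nt, or more than one third of the gene span), and for
intron count; genes are grouped by whether their sense PACs are only
3'UTR, only non-3'UTR, or both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats as sps

from .annotation import GeneModel
from .classification import N3PAS_CATEGORIES, PacCall

log = logging.getLogger(__name__)

SHORT_UTR_CUTOFF = 10  # nt, inclusive
LONG_INTRON_ABS = 800  # nt, strict
LONG_INTRON_FRAC = 1.0 / 3.0  # of gene span, strict

PAC_GROUPS = ("Only3UTR", "Both", "OnlyNon3UTR", "NoPAC")


@dataclass(frozen=True)
class GeneLabels:
    gene_id: str
    atypical5utr: str  # spliced | ambiguous | extreme_short | none
    long_intron: bool
    intron_count: int
    gene_length: int
    pac_group: str


def _utr5_is_spliced(tx) -> bool:
    """An isoform's 5'UTR is spliced when an intron lies wholly or
    partly within its 5'UTR genomic extent."""
    bounds = tx.utr5_bounds()
    if bounds is None:
        return False
    lo, hi = bounds
    return any(s <= hi and e >= lo for s, e in tx.intron_segments)


def label_5utr(gene: GeneModel, short_cutoff: int = SHORT_UTR_CUTOFF) -> str:
    """Atypical-5'UTR label using all annotated isoforms.

    Precedence: spliced > ambiguous > extreme_short > none. A gene
    without any annotated 5'UTR counts as length 0, hence extreme
    short (logged).
    """
    if any(_utr5_is_spliced(tx) for tx in gene.transcripts):
        return "spliced"
    if len(gene.transcripts) >= 2:
        bounds = {tx.utr5_bounds() for tx in gene.transcripts}
        if len(bounds) > 1:
            return "ambiguous"
    utr5_len = gene.longest_tx.utr5_length
    if utr5_len == 0:
        log.info("gene %s has no annotated 5'UTR; counted as extreme short",
                 gene.gene_id)
    if utr5_len <= short_cutoff:
        return "extreme_short"
    return "none"


def label_long_intron(
    gene: GeneModel,
    abs_cutoff: int = LONG_INTRON_ABS,
    frac_cutoff: float = LONG_INTRON_FRAC,
) -> bool:
    """True when any intron of any isoform is longer than ``abs_cutoff``
    nt or longer than ``frac_cutoff`` of the gene span (both strict)."""
    span = gene.span
    for tx in gene.transcripts:
        for s, e in tx.intron_segments:
            ilen = e - s + 1
            if ilen > abs_cutoff or ilen > frac_cutoff * span:
                return True
    return False


def assign_pac_group(gene_id: str, calls: Sequence[PacCall]) -> str:
    """Only3UTR / Both / OnlyNon3UTR / NoPAC from the gene's sense calls."""
    has_3utr = has_n3 = False
    for c in calls:
        if c.host_gene != gene_id:
            continue
        if c.category == "ThreeUTR":
            has_3utr = True
        elif c.category in N3PAS_CATEGORIES:
            has_n3 = True
    if has_3utr and has_n3:
        return "Both"
    if has_3utr:
        return "Only3UTR"
    if has_n3:
        return "OnlyNon3UTR"
    return "NoPAC"


def label_genes(
    genes: Iterable[GeneModel],
    calls: Sequence[PacCall],
    short_cutoff: int = SHORT_UTR_CUTOFF,
) -> list[GeneLabels]:
    by_host: dict[str, list[PacCall]] = {}
    for c in calls:
        if c.host_gene is not None and c.category in (
            N3PAS_CATEGORIES | {"ThreeUTR"}
        ):
            by_host.setdefault(c.host_gene, []).append(c)
    out = []
    for g in genes:
        out.append(
            GeneLabels(
                gene_id=g.gene_id,
                atypical5utr=label_5utr(g, short_cutoff),
                long_intron=label_long_intron(g),
                intron_count=len(g.longest_tx.intron_segments),
                gene_length=g.span,
                pac_group=assign_pac_group(g.gene_id, by_host.get(g.gene_id, [])),
            )
        )
    return out


def intron_count_curve(
    labels: Sequence[GeneLabels],
    calls: Sequence[PacCall],
    max_bin: int | None = None,
) -> pd.DataFrame:
    """Mean n3PAS and 3'UTR PACs per gene, binned by intron count.

    Bins with zero genes are omitted; ``max_bin`` pools all larger
    intron counts into one final bin.
    """
    n3_per_gene: dict[str, int] = {}
    utr3_per_gene: dict[str, int] = {}
    for c in calls:
        if c.host_gene is None:
            continue
        if c.category in N3PAS_CATEGORIES:
            n3_per_gene[c.host_gene] = n3_per_gene.get(c.host_gene, 0) + 1
        elif c.category == "ThreeUTR":
            utr3_per_gene[c.host_gene] = utr3_per_gene.get(c.host_gene, 0) + 1
    rows = []
    bins: dict[int, list[str]] = {}
    for lab in labels:
        b = lab.intron_count
        if max_bin is not None and b > max_bin:
            b = max_bin
        bins.setdefault(b, []).append(lab.gene_id)
    for b in sorted(bins):
        gids = bins[b]
        rows.append(
            {
                "intron_count": b,
                "n_genes": len(gids),
                "mean_n3pas": sum(n3_per_gene.get(g, 0) for g in gids) / len(gids),
                "mean_3utr": sum(utr3_per_gene.get(g, 0) for g in gids) / len(gids),
            }
        )
    return pd.DataFrame(rows)


def intron_length_comparison(
    genes: Iterable[GeneModel],
    calls: Sequence[PacCall],
    high_coverage_min_tags: int = 10,
) -> dict:
    """Compare lengths of longest-transcript introns with vs without a
    CDS-intron PAC.

    Returns the two mean lengths (nt), a Welch t-test P on the raw
    lengths, and the with-PAC mean restricted to high-coverage calls
    (total tags > ``high_coverage_min_tags``).
    """
    intron_calls: dict[str, list[PacCall]] = {}
    for c in calls:
        if c.category == "CdsIntron" and c.host_gene is not None:
            intron_calls.setdefault(c.host_gene, []).append(c)
    with_lens: list[int] = []
    without_lens: list[int] = []
    with_high: list[int] = []
    for g in genes:
        host_calls = intron_calls.get(g.gene_id, [])
        for s, e in g.longest_tx.intron_segments:
            hits = [c for c in host_calls if s <= c.pac.rep_pos <= e]
            ilen = e - s + 1
            if hits:
                with_lens.append(ilen)
                if any(c.pac.total_tags > high_coverage_min_tags for c in hits):
                    with_high.append(ilen)
            else:
                without_lens.append(ilen)
    res = {
        "n_with": len(with_lens),
        "n_without": len(without_lens),
        "mean_with": float(pd.Series(with_lens).mean()) if with_lens else math.nan,
        "mean_without": (
            float(pd.Series(without_lens).mean()) if without_lens else math.nan
        ),
        "mean_with_high_coverage": (
            float(pd.Series(with_high).mean()) if with_high else math.nan
        ),
        "p_value": math.nan,
    }
    if len(with_lens) >= 2 and len(without_lens) >= 2:
        t = sps.ttest_ind(with_lens, without_lens, equal_var=False)
        res["p_value"] = float(t.pvalue)
    return res
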