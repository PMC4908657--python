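"""From aligned poly(A) tags to filtered sites and poly(A) site clusters.

Each aligned tag contributes one observation of a single-base cleavage
position. Identical positions are collapsed into a :class:`PolyASite`
with a tag count, A-rich internal-priming artifacts are removed by
scanning the -10..+5 window around the site, low-support sites
(< 3 tags) are discarded, and the survivors are chained into PACs by
single-linkage clustering along the chromosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import chrom_length, fetch, max_base_run, revcomp

#: window around the cleavage site scanned for genomic A-runs,
#: in transcription-strand coordinates relative to the site (= 0)
PRIMING_WINDOW = (-10, 5)
#: an A-run at least this long inside the window marks internal priming
PRIMING_A_RUN = 8
#: minimum supporting tags for a high-quality site
MIN_TAGS = 3
#: default maximum gap (nt) between consecutive clustered sites
CLUSTER_GAP = 24


@dataclass(frozen=True, order=True)
class PolyASite:
    """A single strand-aware cleavage position with its tag support."""

    chrom: str
    strand: str
    pos: int
    tag_count: int

    def __post_init__(self):
        if self.tag_count < 1:
            raise ValueError("tag_count must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class PAC:
    """A cluster of nearby same-strand sites, summarized by one
    representative site (the member with the most tags)."""

    pac_id: str
    chrom: str
    strand: str
    member_sites: tuple[PolyASite, ...]
    rep_site: PolyASite
    span_start: int
    span_end: int
    total_tags: int

    @property
    def rep_pos(self) -> int:
        return self.rep_site.pos

    @property
    def n_sites(self) -> int:
        return len(self.member_sites)


def collapse_tags(
    records: Iterable[tuple[str, str, int]]
) -> list[PolyASite]:
    """Group raw tag records into one site per (chrom, strand, pos)."""
    counts = Counter((c, s, int(p)) for c, s, p in records)
    sites = [
        PolyASite(c, s, p, n) for (c, s, p), n in counts.items()
    ]
    sites.sort()
    return sites


def priming_window_seq(site: PolyASite, genome) -> str:
    """Strand-oriented sequence of the -10..+5 window around a site.

    The window is truncated at chromosome edges; a window entirely off
    the chromosome raises ``ValueError``.
    """
    lo, hi = PRIMING_WINDOW
    if site.strand == "+":
        start, end = site.pos + lo, site.pos + hi
    else:
        start, end = site.pos - hi, site.pos - lo
    clen = chrom_length(genome, site.chrom)
    start_c, end_c = max(1, start), min(clen, end)
    if start_c > end_c:
        raise ValueError(
            f"priming window for {site.chrom}:{site.pos} lies entirely "
            f"outside the chromosome"
        )
    seq = fetch(genome, site.chrom, start_c, end_c)
    return seq if site.strand == "+" else revcomp(seq)


def internal_priming_filter(site: PolyASite, genome) -> bool:
    """True when the site should be kept (no A-run >= 8 in the window)."""
    return max_base_run(priming_window_seq(site, genome), "A") < PRIMING_A_RUN


def filter_internal_priming(
    sites: Iterable[PolyASite], genome
) -> tuple[list[PolyASite], list[PolyASite]]:
    """Split sites into (kept, dropped-as-internal-priming)."""
    kept, dropped = [], []
    for s in sites:
        (kept if internal_priming_filter(s, genome) else dropped).append(s)
    return kept, dropped


def quality_filter(
    sites: Sequence[PolyASite], min_tags: int = MIN_TAGS
) -> list[PolyASite]:
    """Keep sites supported by at least ``min_tags`` tags (inclusive)."""
    if min_tags < 1:
        raise ValueError("min_tags must be >= 1")
    return [s for s in sites if s.tag_count >= min_tags]


def cluster_sites(
    sites: Sequence[PolyASite], cluster_gap: int = CLUSTER_GAP
) -> list[PAC]:
    """Single-linkage chain sites into PACs per (chrom, strand).

    Consecutive position-sorted sites join the same PAC when their gap
    is at most ``cluster_gap`` nt. The representative site is the
    member with the most tags; ties go to the 3'-most member in the
    transcription direction.
    """
    if cluster_gap < 0:
        raise ValueError("cluster_gap must be >= 0")
    groups: dict[tuple[str, str], list[PolyASite]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.strand), []).append(s)
    pacs: list[PAC] = []
    for (chrom, strand) in sorted(groups):
        members = sorted(groups[(chrom, strand)], key=lambda s: s.pos)
        chains: list[list[PolyASite]] = []
        for s in members:
            if chains and s.pos - chains[-1][-1].pos <= cluster_gap:
                chains[-1].append(s)
            else:
                chains.append([s])
        for chain in chains:
            # 3'-most on '+' is the largest position, on '-' the smallest
            if strand == "+":
                rep = max(chain, key=lambda s: (s.tag_count, s.pos))
            else:
                rep = max(chain, key=lambda s: (s.tag_count, -s.pos))
            pacs.append(
                PAC(
                    pac_id="",
                    chrom=chrom,
                    strand=strand,
                    member_sites=tuple(chain),
                    rep_site=rep,
                    span_start=chain[0].pos,
                    span_end=chain[-1].pos,
                    total_tags=sum(s.tag_count for s in chain),
                )
            )
    pacs.sort(key=lambda p: (p.chrom, p.span_start, p.strand))
    return [
        PAC(
            pac_id=f"PAC{i + 1:05d}",
            chrom=p.chrom,
            strand=p.strand,
            member_sites=p.member_sites,
            rep_site=p.rep_site,
            span_start=p.span_start,
            span_end=p.span_end,
            total_tags=p.total_tags,
        )
        for i, p in enumerate(pacs)
    ]


# ---------------------------------------------------------------------------
# I/O


def read_site_bed(path: str) -> list[PolyASite]:
    """Read sites from the BED6 dialect.

    Columns: chrom, pos-1 (BED start), pos (BED end), name, tag count
    (score column), strand. One line per site.
    """
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"bad BED6 line {lineno} in {path}")
            sites.append(PolyASite(f[0], f[5], int(f[2]), int(f[4])))
    sites.sort()
    return sites


def write_site_bed(sites: Iterable[PolyASite], path: str) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sorted(sites), 1):
            fh.write(
                f"{s.chrom}\t{s.pos - 1}\t{s.pos}\tsite{i:06d}\t"
                f"{s.tag_count}\t{s.strand}\n"
            )


def read_tag_tsv(path: str) -> list[PolyASite]:
    """Read a raw tag stream (chrom, strand, pos TSV) and collapse it."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) != 3:
                raise ValueError(f"bad tag TSV line {lineno} in {path}")
            records.append((f[0], f[1], int(f[2])))
    return collapse_tags(records)


def write_pac_table(pacs: Iterable[PAC], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pac_id\tchrom\tstrand\tspan_start\tspan_end\trep_pos\t"
            "n_sites\ttotal_tags\n"
        )
        for p in pacs:
            fh.write(
                f"{p.pac_id}\t{p.chrom}\t{p.strand}\t{p.span_start}\t"
                f"{p.span_end}\t{p.rep_pos}\t{p.n_sites}\t{p.total_tags}\n"
            )
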