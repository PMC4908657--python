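"""Gene-model and transposable-element annotation handling.

Protein-coding genes are loaded from GFF3 with the conventions used
throughout the package: only the longest transcript of each gene serves
as the classification reference, the transcript terminus is extended by
120 nt in the transcription direction to absorb missing 3'UTR
annotation, and everything outside the union of these extended spans is
intergenic.

All coordinates are 1-based inclusive (GFF3 convention) end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

Interval = tuple[int, int]

#: distance (nt) the transcript terminus is extended in the
#: transcription direction to absorb unannotated 3'UTR ends
EXTENSION_NT = 120

TE_FAMILIES = ("Helitron", "DNA", "LINE", "SINE", "LTR")

_FAMILY_KEYWORDS = {
    "helitron": "Helitron",
    "atrep": "Helitron",
    "rathe": "SINE",
    "line": "LINE",
    "l1": "LINE",
    "sine": "SINE",
    "rathsine": "SINE",
    "ltr": "LTR",
    "copia": "LTR",
    "gypsy": "LTR",
    "dna": "DNA",
    "mudr": "DNA",
    "harbinger": "DNA",
    "hat": "DNA",
    "tc1": "DNA",
    "cacta": "DNA",
    "enspm": "DNA",
    "pogo": "DNA",
    "mariner": "DNA",
}


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform with its segment geometry.

    Segment lists are ordered 5'->3' in the transcription direction;
    each segment is a 1-based inclusive ``(start, end)`` genomic
    interval with ``start <= end`` regardless of strand.
    """

    tx_id: str
    strand: str
    tx_start: int
    tx_end: int
    exon_segments: tuple[Interval, ...]
    cds_exon_segments: tuple[Interval, ...]
    five_utr_segments: tuple[Interval, ...]
    three_utr_segments: tuple[Interval, ...]
    intron_segments: tuple[Interval, ...]

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start + 1

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3'-most transcribed base."""
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def five_prime_end(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def utr5_length(self) -> int:
        return sum(e - s + 1 for s, e in self.five_utr_segments)

    def utr5_bounds(self) -> Interval | None:
        """Genomic (start, end) of the 5'UTR, or None when absent."""
        if not self.five_utr_segments:
            return None
        starts = [s for s, _ in self.five_utr_segments]
        ends = [e for _, e in self.five_utr_segments]
        return (min(starts), max(ends))


@dataclass
class GeneModel:
    """A protein-coding gene with the longest transcript selected."""

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)
    longest_tx: TranscriptModel | None = None
    extended_end: int | None = None

    @property
    def span(self) -> int:
        return self.gene_end - self.gene_start + 1

    @property
    def extended_span(self) -> Interval:
        """Gene span grown to include the 120 nt 3' extension."""
        if self.extended_end is None:
            return (self.gene_start, self.gene_end)
        if self.strand == "+":
            return (self.gene_start, max(self.gene_end, self.extended_end))
        return (min(self.gene_start, self.extended_end), self.gene_end)

    def finalize(self, chrom_length: int | None = None) -> None:
        """Select the longest transcript and compute the extended end.

        Longest is measured as genomic span; ties break on the
        lexicographically smallest transcript id so the choice does not
        depend on input order.
        """
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        self.longest_tx = min(self.transcripts, key=lambda t: (-t.span, t.tx_id))
        term = self.longest_tx.three_prime_end
        if self.strand == "+":
            ext = term + EXTENSION_NT
            if chrom_length is not None and ext > chrom_length:
                warnings.warn(
                    f"gene {self.gene_id}: 3' extension clipped at chromosome end"
                )
                ext = chrom_length
        else:
            ext = term - EXTENSION_NT
            if ext < 1:
                warnings.warn(
                    f"gene {self.gene_id}: 3' extension clipped at chromosome start"
                )
                ext = 1
        self.extended_end = ext


@dataclass(frozen=True)
class TeRecord:
    """One annotated transposable element."""

    te_id: str
    chrom: str
    start: int
    end: int
    family: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"TE record {self.te_id}: start {self.start} > end {self.end}"
            )


def normalize_te_family(raw: str) -> str:
    """Collapse a raw family/superfamily string to one canonical token."""
    low = raw.strip().lower()
    for key, fam in _FAMILY_KEYWORDS.items():
        if key in low:
            return fam
    warnings.warn(f"unknown TE family {raw!r}; recorded as 'Other'")
    return "Other"


# ---------------------------------------------------------------------------
# transcript segment reconstruction


def build_transcript(
    tx_id: str,
    strand: str,
    exons: Sequence[Interval],
    cds: Sequence[Interval] = (),
    five_utr: Sequence[Interval] | None = None,
    three_utr: Sequence[Interval] | None = None,
) -> TranscriptModel:
    """Assemble a TranscriptModel, deriving UTRs and introns.

    UTR segments are reconstructed as exon-minus-CDS (split at the CDS
    genomic bounds) when they are not annotated explicitly. Introns are
    the gaps between consecutive exons.
    """
    exons = sorted(tuple(e) for e in exons)
    if not exons:
        raise ValueError(f"transcript {tx_id} has no exons")
    # CDS features are per exon in well-formed GFF3; clip defensively so
    # a CDS interval spanning an intron cannot leak into intron space
    cds = sorted(
        (max(cs, es), min(ce, ee))
        for cs, ce in (tuple(c) for c in cds)
        for es, ee in exons
        if max(cs, es) <= min(ce, ee)
    )
    tx_start, tx_end = exons[0][0], exons[-1][1]

    introns = [
        (exons[i][1] + 1, exons[i + 1][0] - 1)
        for i in range(len(exons) - 1)
        if exons[i + 1][0] - exons[i][1] > 1
    ]

    if five_utr is None and three_utr is None:
        left_utr: list[Interval] = []
        right_utr: list[Interval] = []
        if cds:
            cds_lo, cds_hi = cds[0][0], cds[-1][1]
            for s, e in exons:
                if s < cds_lo:
                    left_utr.append((s, min(e, cds_lo - 1)))
                if e > cds_hi:
                    right_utr.append((max(s, cds_hi + 1), e))
        if strand == "+":
            utr5, utr3 = left_utr, right_utr
        else:
            utr5, utr3 = right_utr, left_utr
    else:
        utr5 = sorted(tuple(u) for u in (five_utr or ()))
        utr3 = sorted(tuple(u) for u in (three_utr or ()))

    def tx_order(segs):
        segs = sorted(segs)
        return tuple(segs if strand == "+" else segs[::-1])

    return TranscriptModel(
        tx_id=tx_id,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exon_segments=tx_order(exons),
        cds_exon_segments=tx_order(cds),
        five_utr_segments=tx_order(utr5),
        three_utr_segments=tx_order(utr3),
        intron_segments=tx_order(introns),
    )


# ---------------------------------------------------------------------------
# GFF3 I/O

_MRNA_TYPES = {"mRNA", "transcript"}
_UTR5_TYPES = {"five_prime_UTR", "5_UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3_UTR", "three_prime_utr"}


def _validate_gff3(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GFF3 line {lineno} in {path}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"malformed GFF3 line {lineno} in {path}: "
                    f"non-integer coordinates"
                ) from exc


def load_annotation(
    gff3_path: str,
    organelle_exclude: Iterable[str] = (),
    chrom_lengths: dict[str, int] | None = None,
) -> list[GeneModel]:
    """Parse GFF3 into finalized protein-coding gene models.

    Genes on excluded chromosomes (typically the organelles, e.g.
    ``{"ChrC", "ChrM"}``) are dropped, as are genes without any usable
    transcript. Genes carrying a non-protein-coding biotype attribute
    are skipped. When ``chrom_lengths`` is given, 3' extensions are
    clipped at chromosome ends.
    """
    _validate_gff3(gff3_path)
    excluded = set(organelle_exclude)
    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.seqid in excluded:
            continue
        biotype = (
            g.attributes.get("gene_biotype", g.attributes.get("biotype", [None]))
        )[0]
        if biotype is not None and biotype != "protein_coding":
            continue
        gm = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            strand=g.strand,
            gene_start=g.start,
            gene_end=g.end,
        )
        has_mrna = False
        for tx in db.children(g, level=1):
            if tx.featuretype not in _MRNA_TYPES:
                continue
            has_mrna = True
            exons = [(c.start, c.end) for c in db.children(tx, featuretype="exon")]
            if not exons:
                warnings.warn(
                    f"transcript {tx.id} of gene {g.id} has no exons; skipped"
                )
                continue
            cds = [(c.start, c.end) for c in db.children(tx, featuretype="CDS")]
            utr5 = [
                (c.start, c.end)
                for t in _UTR5_TYPES
                for c in db.children(tx, featuretype=t)
            ]
            utr3 = [
                (c.start, c.end)
                for t in _UTR3_TYPES
                for c in db.children(tx, featuretype=t)
            ]
            gm.transcripts.append(
                build_transcript(
                    tx.id,
                    g.strand,
                    exons,
                    cds,
                    five_utr=utr5 or None,
                    three_utr=utr3 or None,
                )
            )
        if not has_mrna:
            # gene without any mRNA child: not usable as protein coding
            continue
        if not gm.transcripts:
            warnings.warn(f"gene {g.id} has no usable transcripts; skipped")
            continue
        gm.transcripts.sort(key=lambda t: t.tx_id)
        clen = chrom_lengths.get(gm.chrom) if chrom_lengths else None
        gm.finalize(chrom_length=clen)
        genes.append(gm)
    genes.sort(key=lambda g: (g.chrom, g.gene_start, g.gene_id))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    """Write gene models back out as GFF3 (gene/mRNA/exon/CDS/UTR rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.gene_start, g.gene_id)):
            attrs = f"ID={g.gene_id};biotype=protein_coding"
            fh.write(
                f"{g.chrom}\tn3pas\tgene\t{g.gene_start}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for tx in g.transcripts:
                fh.write(
                    f"{g.chrom}\tn3pas\tmRNA\t{tx.tx_start}\t{tx.tx_end}\t.\t"
                    f"{g.strand}\t.\tID={tx.tx_id};Parent={g.gene_id}\n"
                )
                rows = [("exon", seg) for seg in tx.exon_segments]
                rows += [("CDS", seg) for seg in tx.cds_exon_segments]
                rows += [("five_prime_UTR", seg) for seg in tx.five_utr_segments]
                rows += [("three_prime_UTR", seg) for seg in tx.three_utr_segments]
                for ftype, (s, e) in sorted(rows, key=lambda r: (r[1], r[0])):
                    phase = "0" if ftype == "CDS" else "."
                    fh.write(
                        f"{g.chrom}\tn3pas\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t"
                        f"{phase}\tID={tx.tx_id}.{ftype}.{s};Parent={tx.tx_id}\n"
                    )


# ---------------------------------------------------------------------------
# intergenic complement


def intergenic_regions(
    genes: Iterable[GeneModel], chrom_lengths: dict[str, int]
) -> list[tuple[str, int, int]]:
    """Strand-agnostic complement of the union of extended gene spans.

    Returns sorted, disjoint ``(chrom, start, end)`` intervals covering
    every base not inside any gene's extended span. Chromosomes with no
    genes are returned whole.
    """
    by_chrom: dict[str, list[Interval]] = {c: [] for c in chrom_lengths}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise KeyError(f"no chromosome length for {g.chrom}")
        clen = chrom_lengths[g.chrom]
        s, e = g.extended_span
        if e > clen:
            warnings.warn(f"gene {g.gene_id} extends past chromosome end; clipped")
            e = clen
        s = max(1, s)
        by_chrom[g.chrom].append((s, e))
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        clen = chrom_lengths[chrom]
        merged: list[list[int]] = []
        for s, e in sorted(by_chrom[chrom]):
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 1
        for s, e in merged:
            if s > cursor:
                out.append((chrom, cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= clen:
            out.append((chrom, cursor, clen))
    return out


# ---------------------------------------------------------------------------
# transposable elements


def load_tes(path: str) -> list[TeRecord]:
    """Load TE annotation from GFF3 or a 5-field TSV.

    The TSV layout is ``id chrom start end family`` (whitespace or tab
    separated). For GFF3, the family is taken from a ``family`` /
    ``Family`` / ``Alias`` attribute when present.
    """
    records: list[TeRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    is_gff = any(
        len(line.rstrip("\n").split("\t")) == 9
        for line in lines
        if line.strip() and not line.startswith("#")
    )
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if is_gff:
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed TE GFF3 line {lineno} in {path}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            te_id = attrs.get("ID", f"TE{lineno}")
            raw_fam = (
                attrs.get("family")
                or attrs.get("Family")
                or attrs.get("Alias")
                or fields[2]
            )
            chrom, start, end = fields[0], int(fields[3]), int(fields[4])
        else:
            fields = line.split()
            if len(fields) != 5:
                raise ValueError(
                    f"malformed TE TSV line {lineno} in {path}: "
                    f"expected 5 fields (id chrom start end family)"
                )
            te_id, chrom, raw_fam = fields[0], fields[1], fields[4]
            start, end = int(fields[2]), int(fields[3])
        fam = raw_fam if raw_fam in TE_FAMILIES else normalize_te_family(raw_fam)
        records.append(TeRecord(te_id, chrom, start, end, fam))
    return records
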