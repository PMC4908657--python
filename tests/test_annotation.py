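"""Gene-model parsing, the 120 nt extension, and the intergenic complement."""

import random

import pytest

from n3pas.annotation import (
    GeneModel,
    TeRecord,
    build_transcript,
    intergenic_regions,
    load_annotation,
    load_tes,
    write_gff3,
)

GFF_HEADER = "##gff-version 3\n"


def _gene_lines(gid, chrom, strand, start, end, exons, cds=(), biotype=None):
    attr = f"ID={gid}" + (f";biotype={biotype}" if biotype else "")
    lines = [f"{chrom}\tsrc\tgene\t{start}\t{end}\t.\t{strand}\t.\t{attr}"]
    lines.append(
        f"{chrom}\tsrc\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
        f"ID={gid}.1;Parent={gid}"
    )
    for s, e in exons:
        lines.append(
            f"{chrom}\tsrc\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={gid}.1"
        )
    for s, e in cds:
        lines.append(
            f"{chrom}\tsrc\tCDS\t{s}\t{e}\t.\t{strand}\t0\tParent={gid}.1"
        )
    return lines


def _write(tmp_path, lines, name="toy.gff3"):
    p = tmp_path / name
    p.write_text(GFF_HEADER + "\n".join(lines) + "\n")
    return str(p)


def test_organelle_genes_excluded(tmp_path):
    lines = []
    for i, chrom in enumerate(["Chr1", "Chr1", "Chr2", "ChrC"]):
        s = 1000 + 5000 * i
        lines += _gene_lines(
            f"g{i}", chrom, "+", s, s + 999,
            exons=[(s, s + 999)], cds=[(s + 100, s + 800)],
        )
    genes = load_annotation(
        _write(tmp_path, lines), organelle_exclude={"ChrC", "ChrM"}
    )
    assert len(genes) == 3
    assert all(g.chrom != "ChrC" for g in genes)


def test_longest_transcript_by_genomic_span(tmp_path):
    lines = _gene_lines("g1", "Chr1", "+", 1000, 2199,
                        exons=[(1000, 2199)], cds=[(1100, 2000)])
    # a second, shorter isoform (span 900 vs 1200)
    lines.append("Chr1\tsrc\tmRNA\t1000\t1899\t.\t+\t.\tID=g1.2;Parent=g1")
    lines.append("Chr1\tsrc\texon\t1000\t1899\t.\t+\t.\tParent=g1.2")
    lines.append("Chr1\tsrc\tCDS\t1100\t1800\t.\t+\t0\tParent=g1.2")
    (genes,) = [load_annotation(_write(tmp_path, lines))[0]]
    assert genes.longest_tx.tx_id == "g1.1"
    assert genes.longest_tx.span == 1200


def test_extension_is_120nt_downstream(tmp_path):
    lines = _gene_lines("g1", "Chr1", "+", 4001, 5000,
                        exons=[(4001, 5000)], cds=[(4101, 4800)])
    lines += _gene_lines("g2", "Chr1", "-", 8001, 9000,
                         exons=[(8001, 9000)], cds=[(8201, 8900)])
    genes = load_annotation(_write(tmp_path, lines))
    plus = next(g for g in genes if g.gene_id == "g1")
    minus = next(g for g in genes if g.gene_id == "g2")
    assert plus.extended_end == 5120
    assert plus.extended_span == (4001, 5120)
    assert minus.extended_end == 7881
    assert minus.extended_span == (7881, 9000)


def test_utr_reconstruction_from_exon_minus_cds(tmp_path):
    lines = _gene_lines(
        "g1", "Chr1", "+", 1000, 2999,
        exons=[(1000, 1400), (1801, 2999)],
        cds=[(1200, 1400), (1801, 2500)],
    )
    (g,) = load_annotation(_write(tmp_path, lines))
    tx = g.longest_tx
    assert tx.five_utr_segments == ((1000, 1199),)
    assert tx.three_utr_segments == ((2501, 2999),)
    assert tx.intron_segments == ((1401, 1800),)
    assert tx.utr5_length == 200


def test_malformed_gff_names_line_number(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text(GFF_HEADER + "Chr1\tsrc\tgene\t100\n")
    with pytest.raises(ValueError, match="line 2"):
        load_annotation(str(p))


def test_longest_tie_breaks_on_tx_id_and_ignores_order(tmp_path):
    base = _gene_lines("g1", "Chr1", "+", 1000, 1999,
                       exons=[(1000, 1999)], cds=[(1100, 1900)])
    extra = [
        "Chr1\tsrc\tmRNA\t1000\t1999\t.\t+\t.\tID=g1.0;Parent=g1",
        "Chr1\tsrc\texon\t1000\t1999\t.\t+\t.\tParent=g1.0",
        "Chr1\tsrc\tCDS\t1100\t1900\t.\t+\t0\tParent=g1.0",
    ]
    (a,) = load_annotation(_write(tmp_path, base + extra, "a.gff3"))
    (b,) = load_annotation(
        _write(tmp_path, base[:1] + extra + base[1:], "b.gff3")
    )
    assert a.longest_tx.tx_id == "g1.0" == b.longest_tx.tx_id


def _mk_gene(gid, chrom, strand, start, end):
    g = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                  gene_start=start, gene_end=end)
    cds = (start + 100, end - 100)
    g.transcripts.append(
        build_transcript(f"{gid}.1", strand, [(start, end)], [cds])
    )
    g.finalize()
    return g


def test_intergenic_complement_single_gene():
    # extended span [101, 600] on a 1000 nt chromosome
    g = _mk_gene("g1", "Chr1", "+", 101, 480)
    assert g.extended_span == (101, 600)
    out = intergenic_regions([g], {"Chr1": 1000})
    assert out == [("Chr1", 1, 100), ("Chr1", 601, 1000)]


def test_intergenic_abutting_genes_leave_no_interior_gap():
    a = _mk_gene("a", "Chr1", "+", 101, 380)  # extended to 500
    b = _mk_gene("b", "Chr1", "+", 501, 800)
    out = intergenic_regions([a, b], {"Chr1": 1200})
    assert out == [("Chr1", 1, 100), ("Chr1", 921, 1200)]


def test_intergenic_partition_bruteforce():
    """Per-base membership in {extended genic, intergenic} is exclusive
    and exhaustive, including overlapping opposite-strand genes."""
    rnd = random.Random(0)
    for _ in range(20):
        clen = 2000
        genes = []
        for i in range(rnd.randint(1, 5)):
            s = rnd.randint(1, clen - 400)
            e = s + rnd.randint(250, 380)
            genes.append(
                _mk_gene(f"g{i}", "Chr1", rnd.choice("+-"), s, min(e, clen - 130))
            )
        inter = intergenic_regions(genes, {"Chr1": clen})
        genic = [False] * (clen + 1)
        for g in genes:
            s, e = g.extended_span
            for p in range(max(1, s), min(clen, e) + 1):
                genic[p] = True
        intergenic = [False] * (clen + 1)
        for _, s, e in inter:
            for p in range(s, e + 1):
                assert not intergenic[p], "overlapping intergenic intervals"
                intergenic[p] = True
        for p in range(1, clen + 1):
            assert genic[p] != intergenic[p]


def test_gff3_round_trip(default_fixture, tmp_path):
    genes = default_fixture.genes[:30]
    path = tmp_path / "rt.gff3"
    write_gff3(genes, str(path))
    back = load_annotation(str(path))
    assert len(back) == len(genes)
    for orig, rt in zip(sorted(genes, key=lambda g: (g.chrom, g.gene_start,
                                                     g.gene_id)), back):
        assert rt.gene_id == orig.gene_id
        assert (rt.gene_start, rt.gene_end, rt.strand) == (
            orig.gene_start, orig.gene_end, orig.strand
        )
        assert rt.extended_end == orig.extended_end
        assert rt.longest_tx.tx_id == orig.longest_tx.tx_id
        for a, b in zip(rt.transcripts, orig.transcripts):
            assert a.five_utr_segments == b.five_utr_segments
            assert a.cds_exon_segments == b.cds_exon_segments
            assert a.intron_segments == b.intron_segments
            assert a.three_utr_segments == b.three_utr_segments


class TestLoadTes:
    def test_tsv_row(self, tmp_path):
        p = tmp_path / "te.tsv"
        p.write_text("AT1TE001\tChr1\t460\t480\tHelitron\n")
        (te,) = load_tes(str(p))
        assert te == TeRecord("AT1TE001", "Chr1", 460, 480, "Helitron")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "te.tsv"
        p.write_text("")
        assert load_tes(str(p)) == []

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "te.tsv"
        p.write_text("TE9\tChr1\t500\t400\tDNA\n")
        with pytest.raises(ValueError, match="TE9"):
            load_tes(str(p))

    def test_unknown_family_becomes_other(self, tmp_path):
        p = tmp_path / "te.tsv"
        p.write_text("TE1\tChr1\t100\t200\tWeirdFam\n")
        with pytest.warns(UserWarning, match="WeirdFam"):
            (te,) = load_tes(str(p))
        assert te.family == "Other"

    def test_gff3_input_with_family_attribute(self, tmp_path):
        p = tmp_path / "te.gff3"
        p.write_text(
            "Chr1\ttair\ttransposable_element\t100\t300\t.\t+\t.\t"
            "ID=AT1TE01;family=RathE1_cons\n"
            "Chr1\ttair\ttransposable_element\t500\t700\t.\t-\t.\t"
            "ID=AT1TE02;Alias=ATCOPIA24\n"
        )
        tes = load_tes(str(p))
        assert [t.family for t in tes] == ["SINE", "LTR"]
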