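"""Six-way classification, the 400 nt rescue, and the category tally."""

import dataclasses

import pytest

from n3pas.annotation import GeneModel, build_transcript
from n3pas.classification import (
    AnnotationIndex,
    PacCall,
    classify_pac,
    classify_pacs,
    reclassify_5utr,
    tally_categories,
)
from n3pas.extraction import PAC, PolyASite
from n3pas.simulate import ScenarioConfig, generate


def _pac(chrom, strand, pos, tags=5, pac_id="P1"):
    s = PolyASite(chrom, strand, pos, tags)
    return PAC(pac_id, chrom, strand, (s,), s, pos, pos, tags)


def _gene(gid, chrom, strand, exons, cds, start=None, end=None):
    start = start if start is not None else min(s for s, _ in exons)
    end = end if end is not None else max(e for _, e in exons)
    g = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                  gene_start=start, gene_end=end)
    g.transcripts.append(build_transcript(f"{gid}.1", strand, exons, cds))
    g.finalize()
    return g


@pytest.fixture(scope="module")
def toy_index():
    # plus-strand gene with 5'UTR, CDS exons, CDS intron, 3'UTR
    a = _gene(
        "gA", "Chr1", "+",
        exons=[(1001, 1200), (1501, 2000), (2301, 3000)],
        cds=[(1101, 1200), (1501, 2000), (2301, 2400)],
    )
    # plus-strand gene whose first intron lies inside the 5'UTR
    b = _gene(
        "gB", "Chr1", "+",
        exons=[(5001, 5100), (5401, 6500)],
        cds=[(5451, 6200)],
    )
    # minus-strand gene
    c = _gene(
        "gC", "Chr1", "-",
        exons=[(9001, 9600), (9901, 10500)],
        cds=[(9201, 9600), (9901, 10400)],
    )
    return AnnotationIndex([a, b, c])


def _paint_oracle():
    """Independent per-base category map for the toy genes, written out
    interval by interval from their geometry."""
    paint = {}

    def mark(strand, lo, hi, cat, host):
        for p in range(lo, hi + 1):
            paint[(strand, p)] = (cat, host)

    # gA (+): utr5 1001-1100, cds 1101-1200/1501-2000/2301-2400,
    # introns 1201-1500 (CDS) and 2001-2300 (CDS), utr3 2401-3000,
    # extension 3001-3120
    mark("+", 1001, 1100, "FiveUTR", "gA")
    mark("+", 1101, 1200, "CdsExon", "gA")
    mark("+", 1201, 1500, "CdsIntron", "gA")
    mark("+", 1501, 2000, "CdsExon", "gA")
    mark("+", 2001, 2300, "CdsIntron", "gA")
    mark("+", 2301, 2400, "CdsExon", "gA")
    mark("+", 2401, 3000, "ThreeUTR", "gA")
    mark("+", 3001, 3120, "ThreeUTR", "gA")
    mark("-", 1001, 3120, "Antisense", "gA")
    # gB (+): utr5 5001-5100 + 5401-5450 with UTR intron 5101-5400
    mark("+", 5001, 5100, "FiveUTR", "gB")
    mark("+", 5101, 5400, "FiveUTR", "gB")
    mark("+", 5401, 5450, "FiveUTR", "gB")
    mark("+", 5451, 6200, "CdsExon", "gB")
    mark("+", 6201, 6500, "ThreeUTR", "gB")
    mark("+", 6501, 6620, "ThreeUTR", "gB")
    mark("-", 5001, 6620, "Antisense", "gB")
    # gC (-): transcription right-to-left; utr5 10401-10500,
    # cds 9901-10400 and 9201-9600, CDS intron 9601-9900,
    # utr3 9001-9200, extension 8881-9000
    mark("-", 10401, 10500, "FiveUTR", "gC")
    mark("-", 9901, 10400, "CdsExon", "gC")
    mark("-", 9601, 9900, "CdsIntron", "gC")
    mark("-", 9201, 9600, "CdsExon", "gC")
    mark("-", 9001, 9200, "ThreeUTR", "gC")
    mark("-", 8881, 9000, "ThreeUTR", "gC")
    mark("+", 8881, 10500, "Antisense", "gC")
    return paint


def test_locate_matches_per_base_oracle(toy_index):
    paint = _paint_oracle()
    for pos in range(1, 11001):
        for strand in "+-":
            cat, host, _ = toy_index.locate("Chr1", strand, pos)
            exp_cat, exp_host = paint.get((strand, pos), ("Intergenic", None))
            assert (cat, host) == (exp_cat, exp_host), (strand, pos)


def test_extension_zone_is_three_utr(toy_index):
    call = classify_pac(_pac("Chr1", "+", 3030), toy_index)
    assert (call.category, call.host_gene, call.subtype) == (
        "ThreeUTR", "gA", "extension"
    )


def test_five_utr_intron_subtype(toy_index):
    call = classify_pac(_pac("Chr1", "+", 5250), toy_index)
    assert (call.category, call.subtype) == ("FiveUTR", "intron")


def test_antisense_and_intergenic(toy_index):
    anti = classify_pac(_pac("Chr1", "-", 1500), toy_index)
    assert (anti.category, anti.host_gene) == ("Antisense", "gA")
    inter = classify_pac(_pac("Chr1", "+", 4000), toy_index)
    assert inter.category == "Intergenic" and inter.host_gene is None


def test_unknown_chromosome_errors(toy_index):
    with pytest.raises(KeyError):
        classify_pac(_pac("Chr9", "+", 100), toy_index)


class TestReclassify:
    def _tandem_index(self):
        up = _gene("up", "Chr1", "+", exons=[(1000, 2000)],
                   cds=[(1100, 1900)])
        down = _gene("down", "Chr1", "+", exons=[(2200, 3400)],
                     cds=[(2801, 3300)])
        return AnnotationIndex([up, down])

    @pytest.mark.parametrize("dist,expect_reclass", [(350, True), (401, False)])
    def test_cutoff_distance(self, dist, expect_reclass):
        index = self._tandem_index()
        pos = 2000 + dist  # upstream terminus at 2000; inside down's 5'UTR
        calls = classify_pacs([_pac("Chr1", "+", pos)], index)
        assert calls[0].category == "FiveUTR"
        out = reclassify_5utr(calls, index, cutoff=400)
        if expect_reclass:
            assert out[0].category == "ThreeUTR"
            assert out[0].host_gene == "up"
            assert out[0].reclassified
        else:
            assert out[0] == calls[0]

    def test_idempotent_and_leaves_other_calls_alone(self):
        index = self._tandem_index()
        calls = classify_pacs(
            [_pac("Chr1", "+", 2350, pac_id="P1"),
             _pac("Chr1", "+", 3000, pac_id="P2"),
             _pac("Chr1", "+", 1500, pac_id="P3")],
            index,
        )
        once = reclassify_5utr(calls, index)
        twice = reclassify_5utr(once, index)
        assert once == twice
        by_id = {c.pac.pac_id: c for c in once}
        assert by_id["P2"].category == "CdsExon"  # untouched
        assert by_id["P3"].category == "CdsExon"
        assert by_id["P1"].reclassified


def test_tally_partition_and_n3pas_aggregate(toy_index):
    pacs = [
        _pac("Chr1", "+", 2500, pac_id="P1"),  # ThreeUTR
        _pac("Chr1", "+", 2600, pac_id="P2"),  # ThreeUTR
        _pac("Chr1", "+", 1300, pac_id="P3"),  # CdsIntron
    ]
    tally = tally_categories(classify_pacs(pacs, toy_index))
    assert tally.loc["n3PAS", "n_pacs"] == 1
    assert tally.loc["ThreeUTR", "n_pacs"] == 2
    assert tally.drop("n3PAS")["n_pacs"].sum() == len(pacs)


def test_tally_empty_input():
    tally = tally_categories([])
    assert (tally["n_pacs"] == 0).all() and (tally["n_tags"] == 0).all()


def test_planted_counts_per_category_recovered():
    """A fixture planted with 10 sites per category yields a table of
    six tens (reclassification/pair/artifact plants disabled)."""
    cfg = ScenarioConfig(
        seed=11, n_genes=80,
        prop_convergent_pair=0.0, prop_divergent_pair=0.0,
        prop_tandem_overlap=0.0, prop_plain=0.58,
        n_sites_five_utr=10, n_sites_cds_exon=10, n_sites_cds_intron=10,
        n_sites_three_utr=10, n_sites_extension=0,
        n_sites_antisense=10, n_sites_intergenic=10,
        n_reclass_exon=0, n_reclass_intron=0,
        n_decoys=0, n_low_count=0, n_te_associated=0, n_te_background=0,
    )
    fx = generate(cfg)
    from n3pas.pipeline import run_all

    res = run_all(
        genes=fx.genes, genome=fx.genome,
        sites=[PolyASite(*r) for r in fx.site_records()],
    )
    tally = res["category_tally"]
    for cat in ("FiveUTR", "CdsExon", "CdsIntron", "ThreeUTR",
                "Intergenic", "Antisense"):
        assert tally.loc[cat, "n_pacs"] == 10, cat


def test_paccall_invariants():
    with pytest.raises(ValueError):
        PacCall(pac=_pac("Chr1", "+", 10), category="Intergenic",
                host_gene="g1")
    with pytest.raises(ValueError):
        PacCall(pac=_pac("Chr1", "+", 10), category="Nowhere", host_gene=None)
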