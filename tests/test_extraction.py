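"""Tag collapse, internal-priming and tag-support filters, clustering."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n3pas.extraction import (
    PAC,
    PolyASite,
    cluster_sites,
    collapse_tags,
    filter_internal_priming,
    internal_priming_filter,
    quality_filter,
    read_site_bed,
    write_site_bed,
)


def _genome_with_window(window_plus: str, pos=100, chrom_len=300):
    """Genome where [pos-10, pos+5] on the + strand equals ``window_plus``."""
    assert len(window_plus) == 16
    seq = list("C" * chrom_len)
    seq[pos - 11 : pos + 5] = window_plus
    return {"Chr1": "".join(seq)}


class TestCollapse:
    def test_grouping_and_strand_key(self):
        recs = [("Chr1", "+", 100)] * 5 + [("Chr1", "-", 100)] * 2
        sites = collapse_tags(recs)
        assert len(sites) == 2
        by_strand = {s.strand: s for s in sites}
        assert by_strand["+"].tag_count == 5
        assert by_strand["-"].tag_count == 2

    def test_tag_conservation(self):
        rnd = random.Random(1)
        recs = [("Chr1", "+", rnd.choice([10, 20, 30, 40])) for _ in range(10)]
        sites = collapse_tags(recs)
        assert sum(s.tag_count for s in sites) == 10
        assert len(sites) == len({r[2] for r in recs})

    def test_empty(self):
        assert collapse_tags([]) == []


class TestInternalPriming:
    def test_run_of_eight_dropped(self):
        g = _genome_with_window("TTTGGAAAAAAAACTG")
        assert not internal_priming_filter(PolyASite("Chr1", "+", 100, 5), g)

    def test_run_of_seven_kept(self):
        g = _genome_with_window("TTTGGAAAAAAACTGG")
        assert internal_priming_filter(PolyASite("Chr1", "+", 100, 5), g)

    def test_minus_strand_uses_reverse_complement(self):
        # genomic T-run reads as an A-run on the minus strand
        seq = list("C" * 300)
        seq[95:103] = "T" * 8  # genomic 96..103, inside [95, 110]
        g = {"Chr1": "".join(seq)}
        site = PolyASite("Chr1", "-", 100, 5)
        # independent oracle: explicit reverse-complement + run scan
        window = g["Chr1"][94:110][::-1].translate(
            str.maketrans("ACGT", "TGCA")
        )
        assert "A" * 8 in window
        assert not internal_priming_filter(site, g)
        assert internal_priming_filter(PolyASite("Chr1", "+", 100, 5), g)

    def test_window_truncated_at_chromosome_edge(self):
        g = {"Chr1": "A" * 6 + "C" * 100}
        # window [-5, 10] clipped to [1, 10]: only 6 As -> kept
        assert internal_priming_filter(PolyASite("Chr1", "+", 5, 3), g)

    def test_window_off_chromosome_errors(self):
        g = {"Chr1": "C" * 50}
        with pytest.raises(ValueError):
            internal_priming_filter(PolyASite("Chr1", "+", 200, 3), g)

    def test_idempotent(self):
        g = _genome_with_window("TTTGGAAAAAAAACTG")
        sites = [PolyASite("Chr1", "+", 100, 5), PolyASite("Chr1", "+", 200, 4)]
        once, _ = filter_internal_priming(sites, g)
        twice, dropped2 = filter_internal_priming(once, g)
        assert once == twice and not dropped2


class TestQualityFilter:
    @pytest.mark.parametrize("count,kept", [(3, True), (2, False), (4, True)])
    def test_inclusive_threshold(self, count, kept):
        sites = [PolyASite("Chr1", "+", 100, count)]
        assert (quality_filter(sites) == sites) is kept

    def test_min_tags_one_is_identity(self):
        sites = [PolyASite("Chr1", "+", p, 1) for p in (5, 10)]
        assert quality_filter(sites, min_tags=1) == sites

    def test_idempotent(self):
        sites = [PolyASite("Chr1", "+", p, c) for p, c in
                 [(10, 1), (20, 3), (30, 7)]]
        assert quality_filter(quality_filter(sites)) == quality_filter(sites)


def _bf_clusters(sites, gap):
    """Brute-force transitive closure over all site pairs."""
    parent = list(range(len(sites)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, a in enumerate(sites):
        for j, b in enumerate(sites):
            if (
                i < j
                and a.chrom == b.chrom
                and a.strand == b.strand
                and abs(a.pos - b.pos) <= gap
            ):
                parent[find(i)] = find(j)
    groups = {}
    for i, s in enumerate(sites):
        groups.setdefault(find(i), set()).add((s.chrom, s.strand, s.pos))
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def test_worked_example(self):
        sites = [
            PolyASite("Chr1", "+", 100, 5),
            PolyASite("Chr1", "+", 120, 4),
            PolyASite("Chr1", "+", 200, 3),
        ]
        pacs = cluster_sites(sites, cluster_gap=24)
        assert _bf_clusters(sites, 24) == {
            frozenset({("Chr1", "+", 100), ("Chr1", "+", 120)}),
            frozenset({("Chr1", "+", 200)}),
        }
        assert [p.n_sites for p in pacs] == [2, 1]
        assert pacs[0].rep_pos == 100
        assert (pacs[0].span_start, pacs[0].span_end) == (100, 120)

    def test_singleton(self):
        (p,) = cluster_sites([PolyASite("Chr1", "-", 50, 9)])
        assert p.rep_pos == 50 and p.span_start == p.span_end == 50
        assert p.total_tags == 9

    @pytest.mark.parametrize("second,expected", [(124, 1), (125, 2)])
    def test_gap_boundary(self, second, expected):
        sites = [PolyASite("Chr1", "+", 100, 3),
                 PolyASite("Chr1", "+", second, 3)]
        assert len(cluster_sites(sites, cluster_gap=24)) == expected
        assert len(_bf_clusters(sites, 24)) == expected

    def test_matches_bruteforce_on_random_instances(self):
        rnd = random.Random(0)
        for trial in range(200):
            gap = rnd.choice([0, 5, 24, 40])
            sites = [
                PolyASite(
                    rnd.choice(["Chr1", "Chr2"]),
                    rnd.choice("+-"),
                    rnd.randint(1, 300),
                    rnd.randint(1, 20),
                )
                for _ in range(rnd.randint(1, 50))
            ]
            sites = list({(s.chrom, s.strand, s.pos): s for s in sites}.values())
            pacs = cluster_sites(sites, cluster_gap=gap)
            got = {
                frozenset((m.chrom, m.strand, m.pos) for m in p.member_sites)
                for p in pacs
            }
            assert got == _bf_clusters(sites, gap)
            assert sum(p.total_tags for p in pacs) == sum(
                s.tag_count for s in sites
            )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["Chr1", "Chr2"]),
                st.sampled_from("+-"),
                st.integers(1, 300),
                st.integers(1, 20),
            ),
            min_size=1,
            max_size=40,
            unique_by=lambda t: (t[0], t[1], t[2]),
        ),
        st.integers(0, 40),
    )
    def test_closure_and_conservation_property(self, raw, gap):
        sites = [PolyASite(*t) for t in raw]
        pacs = cluster_sites(sites, cluster_gap=gap)
        got = {
            frozenset((m.chrom, m.strand, m.pos) for m in p.member_sites)
            for p in pacs
        }
        assert got == _bf_clusters(sites, gap)
        assert sum(p.total_tags for p in pacs) == sum(
            s.tag_count for s in sites
        )
        assert all(p.rep_site.tag_count == max(
            m.tag_count for m in p.member_sites) for p in pacs)

    def test_order_invariance(self):
        rnd = random.Random(3)
        sites = [
            PolyASite("Chr1", rnd.choice("+-"), rnd.randint(1, 200),
                      rnd.randint(1, 9))
            for _ in range(30)
        ]
        sites = list({(s.chrom, s.strand, s.pos): s for s in sites}.values())
        a = cluster_sites(sites)
        shuffled = sites[:]
        rnd.shuffle(shuffled)
        b = cluster_sites(shuffled)
        assert [(p.pac_id, p.member_sites, p.rep_site) for p in a] == [
            (p.pac_id, p.member_sites, p.rep_site) for p in b
        ]

    def test_rep_is_max_count_with_3prime_tie_break(self):
        plus = [PolyASite("Chr1", "+", 100, 5), PolyASite("Chr1", "+", 110, 5)]
        minus = [PolyASite("Chr1", "-", 100, 5), PolyASite("Chr1", "-", 110, 5)]
        assert cluster_sites(plus)[0].rep_pos == 110
        assert cluster_sites(minus)[0].rep_pos == 100
        uneven = [PolyASite("Chr1", "+", 100, 9), PolyASite("Chr1", "+", 110, 5)]
        assert cluster_sites(uneven)[0].rep_pos == 100


def test_bed_round_trip(tmp_path):
    sites = [
        PolyASite("Chr1", "+", 100, 5),
        PolyASite("Chr1", "-", 200, 3),
        PolyASite("Chr2", "+", 50, 12),
    ]
    p = tmp_path / "sites.bed"
    write_site_bed(sites, str(p))
    assert read_site_bed(str(p)) == sorted(sites)
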