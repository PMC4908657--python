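"""Self-contained synthetic fixtures with ground truth for every stage.

The generator emits a genome FASTA, a GFF3 gene annotation, a TE
table and a poly(A)-tag BED together with per-site, per-gene, per-pair
and per-TE ground truth. It emulates the data structure the analyses
assume: clustered cleavage-site microheterogeneity around true sites,
A-rich internal-priming decoys, sites planted in every genic category
(including the 120 nt post-annotation zone), antisense and intergenic
sites, gene architectures with spliced / ambiguous / extreme-short
5'UTRs, long introns and high intron counts, convergent / divergent /
tandem overlapping pairs, and TEs at controlled distances from sites.

Background sequence is i.i.d. uniform over ACGT with A- and T-runs of
eight or more actively broken, and every emitted non-decoy site window
is re-checked and repaired, so the internal-priming property of the
fixture is exact rather than probabilistic.
"""

from __future__ import annotations

import dataclasses
import json
import os
import textwrap
from dataclasses import dataclass, field, replace
from bisect import bisect_left, insort

import numpy as np

from . import annotation as ann
from .annotation import GeneModel, TeRecord, build_transcript, write_gff3
from .classification import AnnotationIndex, N3PAS_CATEGORIES
from .extraction import PRIMING_A_RUN
from ._seq import max_base_run, revcomp

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the default study scenario.

    The defaults describe one compact, fully annotated "desk genome":
    about 200 genes over two chromosomes, ~300 true poly(A) site
    clusters plus planted artifacts, adding up to roughly 5000 tags.
    """

    seed: int = 42
    n_chromosomes: int = 2
    chrom_length: int = 450_000
    n_genes: int = 200
    # per-gene archetype proportions (must sum to 1)
    prop_plain: float = 0.40
    prop_spliced_5utr: float = 0.08
    prop_ambiguous_5utr: float = 0.08
    prop_extreme_short_5utr: float = 0.08
    prop_long_intron: float = 0.10
    prop_high_intron: float = 0.08
    prop_convergent_pair: float = 0.10
    prop_divergent_pair: float = 0.04
    prop_tandem_overlap: float = 0.04
    gap_min: int = 500
    gap_max: int = 1500
    # planted true PACs per category
    n_sites_five_utr: int = 25
    n_sites_cds_exon: int = 25
    n_sites_cds_intron: int = 50
    n_sites_three_utr: int = 120
    n_sites_extension: int = 20
    n_sites_antisense: int = 25
    n_sites_intergenic: int = 25
    five_utr_intron_frac: float = 0.2
    # mis-annotated 5'UTR cases planted 121-400 nt past an upstream gene
    n_reclass_exon: int = 8
    n_reclass_intron: int = 4
    # artifacts
    n_decoys: int = 40
    decoy_a_run: int = 10
    n_low_count: int = 30
    # tag depth: negative binomial, heavy-tailed like real tag data
    tag_nb_mean: float = 8.0
    tag_nb_dispersion: float = 2.0
    # microheterogeneity: extra member sites around each true site
    sites_per_pac_mean: float = 1.5
    jitter_scale: float = 4.0
    jitter_max: int = 20
    member_chain_gap: int = 24
    # convergent-pair planting probabilities
    normal_site_prob: float = 0.7
    opposite_n3pas_prob: float = 0.5
    conv_overlap_min: int = 350
    conv_overlap_max: int = 1000
    # transposable elements
    n_te_associated: int = 40
    n_te_background: int = 60
    te_len_min: int = 30
    te_len_max: int = 80
    te_cutoff: int = 40
    # flank signal model
    a_element_prob: float = 0.85
    # long introns attract intronic sites: choice weight = len ** bias
    intron_length_bias: float = 2.0

    def validate(self) -> None:
        props = [
            self.prop_plain,
            self.prop_spliced_5utr,
            self.prop_ambiguous_5utr,
            self.prop_extreme_short_5utr,
            self.prop_long_intron,
            self.prop_high_intron,
            self.prop_convergent_pair,
            self.prop_divergent_pair,
            self.prop_tandem_overlap,
        ]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("archetype proportions must sum to 1")
        if any(p < 0 for p in props):
            raise ValueError("proportions must be non-negative")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not f.name.startswith("prop_"):
                if v < 0:
                    raise ValueError(f"{f.name} must be non-negative")
        if self.conv_overlap_min > self.conv_overlap_max:
            raise ValueError("conv_overlap_min > conv_overlap_max")
        if self.decoy_a_run < PRIMING_A_RUN:
            raise ValueError("decoy_a_run must be >= the filter's run length")
        if self.jitter_max * 2 + self.member_chain_gap >= 70:
            raise ValueError("jitter too wide for the cluster separation margin")


@dataclass
class TruthSite:
    """Ground truth for one emitted member site."""

    site_id: str
    chrom: str
    strand: str
    pos: int
    tag_count: int
    true_pac: str
    category: str  # expected final category (after reclassification)
    host_gene: str | None
    subtype: str | None
    is_rep: bool
    is_decoy: bool = False
    is_low_count: bool = False
    reclassified: bool = False


@dataclass
class Fixture:
    """In-memory fixture bundle plus ground truth."""

    config: ScenarioConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    gene_truth: dict[str, dict]
    tes: list[TeRecord]
    te_truth: list[dict]
    sites: list[TruthSite]
    pair_truth: list[dict]
    conjunction_truth: dict

    @property
    def real_sites(self) -> list[TruthSite]:
        return [s for s in self.sites if not s.is_decoy and not s.is_low_count]

    def site_records(self) -> list[tuple[str, str, int, int]]:
        return [(s.chrom, s.strand, s.pos, s.tag_count) for s in self.sites]

    def truth_by_pos(self) -> dict[tuple[str, str, int], TruthSite]:
        return {(s.chrom, s.strand, s.pos): s for s in self.sites}

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "genome.fa"),
            "gff": os.path.join(outdir, "genes.gff3"),
            "te": os.path.join(outdir, "tes.tsv"),
            "tags": os.path.join(outdir, "tags.bed"),
            "truth_sites": os.path.join(outdir, "truth_sites.tsv"),
            "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
            "truth_pairs": os.path.join(outdir, "truth_pairs.tsv"),
            "truth_tes": os.path.join(outdir, "truth_tes.tsv"),
            "config": os.path.join(outdir, "scenario.json"),
        }
        with open(paths["fasta"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                fh.write(textwrap.fill(self.genome[chrom], 70))
                fh.write("\n")
        write_gff3(self.genes, paths["gff"])
        with open(paths["te"], "w") as fh:
            for te in self.tes:
                fh.write(
                    f"{te.te_id}\t{te.chrom}\t{te.start}\t{te.end}\t{te.family}\n"
                )
        with open(paths["tags"], "w") as fh:
            for s in sorted(self.sites, key=lambda s: (s.chrom, s.pos, s.strand)):
                fh.write(
                    f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.site_id}\t"
                    f"{s.tag_count}\t{s.strand}\n"
                )
        with open(paths["truth_sites"], "w") as fh:
            fh.write(
                "site_id\tchrom\tstrand\tpos\ttag_count\ttrue_pac\tcategory\t"
                "host_gene\tsubtype\tis_rep\tis_decoy\tis_low_count\t"
                "reclassified\n"
            )
            for s in self.sites:
                fh.write(
                    f"{s.site_id}\t{s.chrom}\t{s.strand}\t{s.pos}\t"
                    f"{s.tag_count}\t{s.true_pac}\t{s.category}\t"
                    f"{s.host_gene or '.'}\t{s.subtype or '.'}\t{int(s.is_rep)}\t"
                    f"{int(s.is_decoy)}\t{int(s.is_low_count)}\t"
                    f"{int(s.reclassified)}\n"
                )
        with open(paths["truth_genes"], "w") as fh:
            fh.write(
                "gene_id\tarchetype\tatypical5utr\tlong_intron\tintron_count\n"
            )
            for g in self.genes:
                t = self.gene_truth[g.gene_id]
                fh.write(
                    f"{g.gene_id}\t{t['archetype']}\t{t['atypical5utr']}\t"
                    f"{int(t['long_intron'])}\t{t['intron_count']}\n"
                )
        with open(paths["truth_pairs"], "w") as fh:
            fh.write("gene_a\tgene_b\torientation\toverlap_len\n")
            for p in self.pair_truth:
                fh.write(
                    f"{p['gene_a']}\t{p['gene_b']}\t{p['orientation']}\t"
                    f"{p['overlap_len']}\n"
                )
        with open(paths["truth_tes"], "w") as fh:
            fh.write("te_id\ttarget_pac\tdistance\tfamily\tcategory_class\n")
            for t in self.te_truth:
                fh.write(
                    f"{t['te_id']}\t{t['target_pac']}\t{t['distance']}\t"
                    f"{t['family']}\t{t['category_class']}\n"
                )
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


# ---------------------------------------------------------------------------
# gene templates (transcription-relative coordinates)


def _nb(rng, mean, disp):
    return int(rng.negative_binomial(disp, disp / (disp + mean)))


@dataclass
class _Template:
    utr5: int
    exon_lens: list[int]
    intron_lens: list[int]
    utr3: int
    iso2_shift: int = 0  # ambiguous genes: second isoform starts later

    @property
    def length(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)


def _finish(t: _Template) -> _Template:
    # guarantee at least 100 nt of CDS by padding the last exon
    deficit = t.utr5 + t.utr3 + 100 - sum(t.exon_lens)
    if deficit > 0:
        t.exon_lens[-1] += deficit
    return t


def _template(rng, archetype: str) -> _Template:
    return _finish(_template_raw(rng, archetype))


def _template_raw(rng, archetype: str) -> _Template:
    def exons(n, lo=200, hi=400, last_lo=300, last_hi=500):
        lens = [int(rng.integers(lo, hi + 1)) for _ in range(n)]
        lens[-1] = int(rng.integers(last_lo, last_hi + 1))
        return lens

    def introns(n, lo=80, hi=250):
        return [int(rng.integers(lo, hi + 1)) for _ in range(n)]

    if archetype in ("plain", "pair_member"):
        n_int = int(rng.integers(2, 5)) if archetype == "pair_member" else int(
            rng.integers(0, 5)
        )
        ex = exons(n_int + 1)
        return _Template(
            utr5=int(rng.integers(30, 121)),
            exon_lens=ex,
            intron_lens=introns(n_int),
            utr3=int(rng.integers(120, 251)),
        )
    if archetype == "spliced_5utr":
        n_int = int(rng.integers(2, 5))
        ex = exons(n_int + 1)
        ex[0] = int(rng.integers(50, 81))
        return _Template(
            utr5=ex[0] + int(rng.integers(40, 100)),
            exon_lens=ex,
            intron_lens=introns(n_int),
            utr3=int(rng.integers(120, 251)),
        )
    if archetype == "ambiguous_5utr":
        n_int = int(rng.integers(1, 5))
        return _Template(
            utr5=int(rng.integers(80, 121)),
            exon_lens=exons(n_int + 1),
            intron_lens=introns(n_int),
            utr3=int(rng.integers(120, 251)),
            iso2_shift=int(rng.integers(20, 61)),
        )
    if archetype == "extreme_short_5utr":
        n_int = int(rng.integers(0, 5))
        return _Template(
            utr5=int(rng.integers(3, 11)),
            exon_lens=exons(n_int + 1),
            intron_lens=introns(n_int),
            utr3=int(rng.integers(120, 251)),
        )
    if archetype == "long_intron":
        n_int = int(rng.integers(2, 5))
        ilens = introns(n_int)
        ilens[int(rng.integers(0, n_int))] = int(rng.integers(900, 1501))
        return _Template(
            utr5=int(rng.integers(30, 121)),
            exon_lens=exons(n_int + 1),
            intron_lens=ilens,
            utr3=int(rng.integers(120, 251)),
        )
    if archetype == "high_intron":
        n_int = int(rng.integers(10, 15))
        return _Template(
            utr5=int(rng.integers(30, 121)),
            exon_lens=exons(n_int + 1, lo=150, hi=250, last_lo=300, last_hi=400),
            intron_lens=introns(n_int),
            utr3=int(rng.integers(120, 251)),
        )
    if archetype == "reclass_exon":
        utr5 = int(rng.integers(180, 261))
        ex = exons(1)
        ex[0] = utr5 + int(rng.integers(120, 201))
        return _Template(utr5=utr5, exon_lens=ex, intron_lens=[], utr3=int(
            rng.integers(120, 201)))
    if archetype == "reclass_intron":
        intr0 = int(rng.integers(150, 261))
        ex = [60] + exons(2, lo=250, hi=400)[:2]
        il = [intr0] + introns(1)
        return _Template(
            utr5=60 + int(rng.integers(30, 80)),
            exon_lens=ex,
            intron_lens=il,
            utr3=int(rng.integers(120, 201)),
        )
    raise ValueError(f"unknown archetype {archetype!r}")


def _rel_intervals(t: _Template):
    """Exon/CDS/UTR intervals in 1-based gene-relative '+'-orientation
    coordinates, given transcript-order template lengths."""
    exons = []
    pos = 1
    for i, elen in enumerate(t.exon_lens):
        exons.append((pos, pos + elen - 1))
        pos += elen
        if i < len(t.intron_lens):
            pos += t.intron_lens[i]
    tx_len = sum(t.exon_lens)

    def tx2rel(txpos):
        acc = 0
        for (s, e) in exons:
            if txpos <= acc + (e - s + 1):
                return s + (txpos - acc - 1)
            acc += e - s + 1
        raise ValueError("transcript position outside transcript")

    cds_rel = (tx2rel(t.utr5 + 1), tx2rel(tx_len - t.utr3))
    return exons, cds_rel, tx_len


def _clip_segs(exons, lo, hi):
    out = []
    for s, e in exons:
        a, b = max(s, lo), min(e, hi)
        if a <= b:
            out.append((a, b))
    return out


def _place_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    gene_start: int,
    t: _Template,
) -> GeneModel:
    exons_rel, (cds_lo, cds_hi), _ = _rel_intervals(t)
    L = t.length
    gene_end = gene_start + L - 1

    def to_genomic(iv):
        s, e = iv
        if strand == "+":
            return (gene_start + s - 1, gene_start + e - 1)
        return (gene_end - e + 1, gene_end - s + 1)

    exons_g = [to_genomic(iv) for iv in exons_rel]
    cds_g = [to_genomic(iv) for iv in _clip_segs(exons_rel, cds_lo, cds_hi)]
    utr5_g = [to_genomic(iv) for iv in _clip_segs(exons_rel, 1, cds_lo - 1)]
    utr3_g = [to_genomic(iv) for iv in _clip_segs(exons_rel, cds_hi + 1, L)]

    gm = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        gene_start=gene_start,
        gene_end=gene_end,
    )
    gm.transcripts.append(
        build_transcript(
            f"{gene_id}.1", strand, exons_g, cds_g,
            five_utr=utr5_g or None, three_utr=utr3_g or None,
        )
    )
    if t.iso2_shift:
        # second isoform with a shorter first exon: same CDS, shifted
        # 5'UTR start -> "ambiguous" 5'UTR annotation
        d = t.iso2_shift
        ex2 = list(exons_rel)
        s0, e0 = ex2[0]
        ex2[0] = (s0 + d, e0)
        exons2_g = [to_genomic(iv) for iv in ex2]
        cds2_g = [to_genomic(iv) for iv in _clip_segs(ex2, cds_lo, cds_hi)]
        utr5_2 = [to_genomic(iv) for iv in _clip_segs(ex2, 1 + d, cds_lo - 1)]
        utr3_2 = [to_genomic(iv) for iv in _clip_segs(ex2, cds_hi + 1, L)]
        gm.transcripts.append(
            build_transcript(
                f"{gene_id}.2", strand, exons2_g, cds2_g,
                five_utr=utr5_2 or None, three_utr=utr3_2 or None,
            )
        )
    gm.transcripts.sort(key=lambda tx: tx.tx_id)
    gm.finalize()
    return gm


# ---------------------------------------------------------------------------
# generator


class _SepTracker:
    """Minimum-separation bookkeeping for planted representative sites."""

    def __init__(self, same_strand_min=70, any_min=50):
        self.same = same_strand_min
        self.any = any_min
        self._by_strand: dict[tuple[str, str], list[int]] = {}
        self._all: dict[str, list[int]] = {}

    @staticmethod
    def _near(lst, pos, d):
        i = bisect_left(lst, pos)
        for j in (i - 1, i):
            if 0 <= j < len(lst) and abs(lst[j] - pos) < d:
                return True
        return False

    def ok(self, chrom, strand, pos):
        if self._near(self._all.get(chrom, []), pos, self.any):
            return False
        return not self._near(
            self._by_strand.get((chrom, strand), []), pos, self.same
        )

    def add(self, chrom, strand, pos):
        insort(self._all.setdefault(chrom, []), pos)
        insort(self._by_strand.setdefault((chrom, strand), []), pos)

    def positions(self, chrom):
        return self._all.get(chrom, [])


class _Generator:
    def __init__(self, config: ScenarioConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.chrom_names = [f"Chr{i + 1}" for i in range(config.n_chromosomes)]
        self.seq = {
            c: self._background(config.chrom_length) for c in self.chrom_names
        }
        self.genes: list[GeneModel] = []
        self.gene_truth: dict[str, dict] = {}
        self.gene_archetype: dict[str, str] = {}
        self.pair_truth: list[dict] = []
        self.conv_pairs: list[tuple[GeneModel, GeneModel, int, int]] = []
        self.sep = _SepTracker()
        self.sites: list[TruthSite] = []
        self.tes: list[TeRecord] = []
        self.te_truth: list[dict] = []
        self.conjunction_truth: dict = {}
        self._pac_n = 0
        self._site_n = 0

    # -- sequence ----------------------------------------------------------

    def _background(self, n: int) -> np.ndarray:
        arr = _BASE_CODES[self.rng.integers(0, 4, size=n)]
        for code, repl in ((ord("A"), ord("C")), (ord("T"), ord("G"))):
            mask = arr == code
            idx = np.arange(n)
            last_other = np.maximum.accumulate(np.where(~mask, idx, -1))
            runlen = np.where(mask, idx - last_other, 0)
            # cap runs at 7 by replacing every 8th base of a run
            arr[(runlen > 0) & (runlen % PRIMING_A_RUN == 0)] = repl
        return arr

    def _write_seq(self, chrom, start, values):
        self.seq[chrom][start - 1 : start - 1 + len(values)] = values

    def _oriented_window(self, chrom, strand, pos):
        arr = self.seq[chrom]
        if strand == "+":
            w = arr[pos - 11 : pos + 5]
            return w.tobytes().decode()
        w = arr[pos - 6 : pos + 10]
        return revcomp(w.tobytes().decode())

    # -- placement ---------------------------------------------------------

    def _units(self):
        cfg = self.cfg
        n = cfg.n_genes
        n_conv = round(cfg.prop_convergent_pair * n / 2)
        n_div = round(cfg.prop_divergent_pair * n / 2)
        n_tan = round(cfg.prop_tandem_overlap * n / 2)
        singles_total = n - 2 * (n_conv + n_div + n_tan)
        single_counts = {
            "spliced_5utr": round(cfg.prop_spliced_5utr * n),
            "ambiguous_5utr": round(cfg.prop_ambiguous_5utr * n),
            "extreme_short_5utr": round(cfg.prop_extreme_short_5utr * n),
            "long_intron": round(cfg.prop_long_intron * n),
            "high_intron": round(cfg.prop_high_intron * n),
        }
        used = sum(single_counts.values())
        if used > singles_total:
            raise ValueError("archetype proportions leave no room for plain genes")
        single_counts["plain"] = singles_total - used
        units = [("single", a) for a, c in single_counts.items() for _ in range(c)]
        units += [("convergent", None)] * n_conv
        units += [("divergent", None)] * n_div
        units += [("tandem", None)] * n_tan
        units = [units[i] for i in self.rng.permutation(len(units))]
        units += [("reclass", "exon")] * cfg.n_reclass_exon
        units += [("reclass", "intron")] * cfg.n_reclass_intron
        return units

    def _archetype_label(self, archetype: str) -> tuple[str, bool]:
        """Expected (atypical5utr, long_intron) label for an archetype.

        Template bounds guarantee no accidental qualification: introns
        are capped at 260 nt while the non-intron span always exceeds
        twice that, except in the long_intron archetype.
        """
        atypical = {
            "spliced_5utr": "spliced",
            "ambiguous_5utr": "ambiguous",
            "extreme_short_5utr": "extreme_short",
            "reclass_intron": "spliced",
        }.get(archetype, "none")
        return atypical, archetype == "long_intron"

    def _register_gene(self, g: GeneModel, archetype: str):
        atypical, long_intron = self._archetype_label(archetype)
        self.genes.append(g)
        self.gene_archetype[g.gene_id] = archetype
        self.gene_truth[g.gene_id] = {
            "archetype": archetype,
            "atypical5utr": atypical,
            "long_intron": long_intron,
            "intron_count": len(g.longest_tx.intron_segments),
        }

    def place_genes(self):
        cfg = self.cfg
        rng = self.rng
        units = self._units()
        chrom_i = 0
        cursor = 1000
        gid = 0

        def next_id():
            nonlocal gid
            gid += 1
            return f"G{gid:04d}"

        margin = 1500
        for kind, arg in units:
            gap = int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
            if kind == "single":
                t = _template(rng, arg)
                extent = t.length
            elif kind in ("convergent", "divergent", "tandem"):
                t1 = _template(rng, "pair_member")
                t2 = _template(rng, "pair_member")
                if kind == "convergent":
                    dmax = min(t1.length, t2.length) - 250
                    if dmax < cfg.conv_overlap_min:
                        raise ValueError("pair genes too short for overlap range")
                    d = int(rng.integers(
                        cfg.conv_overlap_min, min(dmax, cfg.conv_overlap_max) + 1
                    ))
                elif kind == "divergent":
                    d = int(rng.integers(100, min(500, min(t1.length, t2.length) - 250)))
                else:
                    d = int(rng.integers(100, 301))
                extent = t1.length + t2.length - d
            else:  # reclass
                t_u = _template(rng, "plain")
                t_d = _template(rng, f"reclass_{arg}")
                g_inner = int(rng.integers(140, 201))
                extent = t_u.length + g_inner + t_d.length
            while cursor + gap + extent > cfg.chrom_length - margin:
                chrom_i += 1
                if chrom_i >= len(self.chrom_names):
                    raise ValueError(
                        "genes do not fit on the configured chromosomes"
                    )
                cursor = 1000
            chrom = self.chrom_names[chrom_i]
            start = cursor + gap

            if kind == "single":
                strand = "+" if rng.random() < 0.5 else "-"
                self._register_gene(
                    _place_gene(next_id(), chrom, strand, start, t), arg
                )
            elif kind == "convergent":
                a = _place_gene(next_id(), chrom, "+", start, t1)
                b_start = a.gene_end - d + 1
                b = _place_gene(next_id(), chrom, "-", b_start, t2)
                self._register_gene(a, "pair_member")
                self._register_gene(b, "pair_member")
                lo, hi = b.gene_start, a.gene_end
                self.conv_pairs.append((a, b, lo, hi))
                self.pair_truth.append(
                    {"gene_a": a.gene_id, "gene_b": b.gene_id,
                     "orientation": "convergent", "overlap_len": d}
                )
            elif kind == "divergent":
                a = _place_gene(next_id(), chrom, "-", start, t1)
                b = _place_gene(next_id(), chrom, "+", a.gene_end - d + 1, t2)
                self._register_gene(a, "pair_member")
                self._register_gene(b, "pair_member")
                self.pair_truth.append(
                    {"gene_a": a.gene_id, "gene_b": b.gene_id,
                     "orientation": "divergent", "overlap_len": d}
                )
            elif kind == "tandem":
                strand = "+" if rng.random() < 0.5 else "-"
                a = _place_gene(next_id(), chrom, strand, start, t1)
                b = _place_gene(next_id(), chrom, strand, a.gene_end - d + 1, t2)
                self._register_gene(a, "pair_member")
                self._register_gene(b, "pair_member")
                self.pair_truth.append(
                    {"gene_a": a.gene_id, "gene_b": b.gene_id,
                     "orientation": "same", "overlap_len": d}
                )
            else:  # reclass pair: upstream gene U, downstream gene D
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    u = _place_gene(next_id(), chrom, "+", start, t_u)
                    d_start = u.gene_end + g_inner
                    dg = _place_gene(next_id(), chrom, "+", d_start, t_d)
                else:
                    dg = _place_gene(next_id(), chrom, "-", start, t_d)
                    u = _place_gene(
                        next_id(), chrom, "-", dg.gene_end + g_inner, t_u
                    )
                self._register_gene(u, "plain")
                self._register_gene(dg, f"reclass_{arg}")
            cursor = max(g.gene_end for g in self.genes[-2:]) \
                if kind != "single" else start + extent - 1
            cursor = max(cursor, start + extent - 1)
        if not self.genes:
            raise ValueError("no genes generated")

    # -- site planting -----------------------------------------------------

    def _tag_counts(self, n_members: int) -> list[int]:
        cfg = self.cfg
        rep = 4 + _nb(self.rng, cfg.tag_nb_mean, cfg.tag_nb_dispersion)
        counts = [rep]
        for _ in range(n_members - 1):
            counts.append(
                3 + min(_nb(self.rng, cfg.tag_nb_mean, cfg.tag_nb_dispersion),
                        rep - 4)
            )
        return counts

    def _member_offsets(self) -> list[int]:
        cfg = self.cfg
        n_extra = int(self.rng.poisson(max(cfg.sites_per_pac_mean - 1, 0)))
        if n_extra == 0:
            return []
        raw = np.rint(
            self.rng.laplace(0.0, cfg.jitter_scale, size=n_extra)
        ).astype(int)
        raw = np.clip(raw, -cfg.jitter_max, cfg.jitter_max)
        offs = sorted({int(o) for o in raw if o != 0})
        # keep only offsets chained to the representative site so a true
        # PAC never splits under the default clustering gap
        kept = []
        prev = 0
        for o in [o for o in offs if o > 0]:
            if o - prev <= cfg.member_chain_gap:
                kept.append(o)
                prev = o
        prev = 0
        for o in [o for o in offs if o < 0][::-1]:
            if prev - o <= cfg.member_chain_gap:
                kept.append(o)
                prev = o
        return sorted(kept)

    def _plant(
        self,
        chrom: str,
        strand: str,
        pos: int,
        category: str,
        host: str | None,
        subtype: str | None,
        bounds: tuple[int, int],
        reclassified: bool = False,
        singleton: bool = False,
    ) -> str:
        self._pac_n += 1
        pac_id = f"TPAC{self._pac_n:04d}"
        offsets = [] if singleton else self._member_offsets()
        members = [0] + [
            o for o in offsets if bounds[0] <= pos + o <= bounds[1]
        ]
        counts = self._tag_counts(len(members))
        for off, cnt in zip(members, counts):
            self._site_n += 1
            self.sites.append(
                TruthSite(
                    site_id=f"S{self._site_n:05d}",
                    chrom=chrom,
                    strand=strand,
                    pos=pos + off,
                    tag_count=cnt,
                    true_pac=pac_id,
                    category=category,
                    host_gene=host,
                    subtype=subtype,
                    is_rep=(off == 0),
                    reclassified=reclassified,
                )
            )
        self.sep.add(chrom, strand, pos)
        return pac_id

    def _try_positions(self, lo, hi, chrom, strand, tries=60):
        span = hi - lo
        if span < 0:
            return None
        for _ in range(tries):
            pos = int(self.rng.integers(lo, hi + 1))
            if self.sep.ok(chrom, strand, pos):
                return pos
        return None

    def plant_generic(self, index: AnnotationIndex):
        cfg = self.cfg
        rng = self.rng
        singles = [
            g for g in self.genes
            if self.gene_archetype[g.gene_id] in (
                "plain", "spliced_5utr", "ambiguous_5utr",
                "extreme_short_5utr", "long_intron", "high_intron",
            )
        ]
        spliced = [g for g in singles
                   if self.gene_archetype[g.gene_id] == "spliced_5utr"]
        wide_utr5 = [g for g in singles
                     if g.longest_tx.utr5_length >= 30
                     and self.gene_archetype[g.gene_id] != "spliced_5utr"]

        def plant_in_segment(gene, seg, category, subtype, margin=2,
                             extra_check=None):
            lo, hi = seg[0] + margin, seg[1] - margin
            for _ in range(40):
                pos = self._try_positions(lo, hi, gene.chrom, gene.strand)
                if pos is None:
                    return False
                cat, host, sub = index.locate(gene.chrom, gene.strand, pos)
                if (cat, host) != (category, gene.gene_id):
                    continue
                if extra_check and not extra_check(pos):
                    continue
                self._plant(gene.chrom, gene.strand, pos, category,
                            gene.gene_id, subtype,
                            (max(seg[0], lo - margin), min(seg[1], hi + margin)))
                return True
            return False

        def no_reclass(gene):
            def check(pos):
                found = index.upstream_terminus(
                    gene.chrom, gene.strand, pos, exclude=gene.gene_id
                )
                return found is None or found[1] > 430
            return check

        # 5'UTR sites: mostly exonic, a fraction inside 5'UTR introns
        n_intronic = round(cfg.n_sites_five_utr * cfg.five_utr_intron_frac)
        for i in range(cfg.n_sites_five_utr):
            for _ in range(40):
                if i < n_intronic and spliced:
                    g = spliced[int(rng.integers(len(spliced)))]
                    tx = g.longest_tx
                    ub = tx.utr5_bounds()
                    cands = [iv for iv in tx.intron_segments
                             if iv[0] <= ub[1] and iv[1] >= ub[0]]
                    if not cands:
                        continue
                    seg, subtype = cands[0], "intron"
                else:
                    if not wide_utr5:
                        break
                    g = wide_utr5[int(rng.integers(len(wide_utr5)))]
                    seg, subtype = g.longest_tx.five_utr_segments[0], "exon"
                if plant_in_segment(g, seg, "FiveUTR", subtype,
                                    extra_check=no_reclass(g)):
                    break

        # CDS exon sites
        for _ in range(cfg.n_sites_cds_exon):
            for _ in range(40):
                g = singles[int(rng.integers(len(singles)))]
                segs = [s for s in g.longest_tx.cds_exon_segments
                        if s[1] - s[0] >= 60]
                if not segs:
                    continue
                seg = segs[int(rng.integers(len(segs)))]
                if plant_in_segment(g, seg, "CdsExon", "exon", margin=5):
                    break

        # CDS intron sites, biased toward long introns
        cds_introns = []
        for g in singles:
            tx = g.longest_tx
            if not tx.cds_exon_segments:
                continue
            cds_lo = min(s for s, _ in tx.cds_exon_segments)
            cds_hi = max(e for _, e in tx.cds_exon_segments)
            for s, e in tx.intron_segments:
                if s > cds_lo and e < cds_hi:
                    cds_introns.append((g, (s, e)))
        if cds_introns and cfg.n_sites_cds_intron:
            weights = np.array(
                [(e - s + 1) ** cfg.intron_length_bias
                 for _, (s, e) in cds_introns], dtype=float
            )
            weights /= weights.sum()
            for _ in range(cfg.n_sites_cds_intron):
                for _ in range(40):
                    k = int(rng.choice(len(cds_introns), p=weights))
                    g, seg = cds_introns[k]
                    if plant_in_segment(g, seg, "CdsIntron", "intron"):
                        break

        # 3'UTR sites
        for _ in range(cfg.n_sites_three_utr):
            for _ in range(40):
                g = singles[int(rng.integers(len(singles)))]
                segs = g.longest_tx.three_utr_segments
                if not segs:
                    continue
                if plant_in_segment(g, segs[0], "ThreeUTR", "exon"):
                    break

        # post-annotation extension zone sites
        for _ in range(cfg.n_sites_extension):
            for _ in range(40):
                g = singles[int(rng.integers(len(singles)))]
                term = g.longest_tx.three_prime_end
                if g.strand == "+":
                    seg = (term + 3, term + 115)
                else:
                    seg = (term - 115, term - 3)
                if plant_in_segment(g, seg, "ThreeUTR", "extension", margin=0):
                    break

        # antisense sites: inside a gene span, on the opposite strand
        for _ in range(cfg.n_sites_antisense):
            for _ in range(40):
                g = singles[int(rng.integers(len(singles)))]
                strand = "-" if g.strand == "+" else "+"
                segs = [s for s in g.longest_tx.cds_exon_segments
                        if s[1] - s[0] >= 60]
                if not segs:
                    continue
                seg = segs[int(rng.integers(len(segs)))]
                pos = self._try_positions(seg[0] + 5, seg[1] - 5, g.chrom, strand)
                if pos is None:
                    continue
                cat, host, _ = index.locate(g.chrom, strand, pos)
                if cat != "Antisense" or host != g.gene_id:
                    continue
                self._plant(g.chrom, strand, pos, "Antisense", g.gene_id,
                            None, seg)
                break

        # intergenic sites: well away from every extended gene span
        chrom_lengths = {c: cfg.chrom_length for c in self.chrom_names}
        gaps = [
            (c, s, e) for c, s, e in ann.intergenic_regions(
                self.genes, chrom_lengths
            )
            if e - s >= 300 and s > 200 and e < cfg.chrom_length - 200
        ]
        for _ in range(cfg.n_sites_intergenic):
            for _ in range(40):
                c, s, e = gaps[int(rng.integers(len(gaps)))]
                strand = "+" if rng.random() < 0.5 else "-"
                pos = self._try_positions(s + 140, e - 140, c, strand)
                if pos is None:
                    continue
                cat, host, _ = index.locate(c, strand, pos)
                if cat != "Intergenic":
                    continue
                self._plant(c, strand, pos, "Intergenic", None, None,
                            (s + 120, e - 120))
                break

    def plant_reclass(self, index: AnnotationIndex):
        """Sites in a downstream gene's 5'UTR, 121-400 nt past the
        upstream gene's terminus: classified FiveUTR first, relabeled
        ThreeUTR of the upstream gene by the 400 nt rule."""
        cutoff = 400
        for gene in self.genes:
            arch = self.gene_archetype[gene.gene_id]
            if arch not in ("reclass_exon", "reclass_intron"):
                continue
            found_any = False
            tx = gene.longest_tx
            if arch == "reclass_exon":
                seg = tx.five_utr_segments[0]
                subtype = "exon"
            else:
                ub = tx.utr5_bounds()
                cands = [iv for iv in tx.intron_segments
                         if iv[0] <= ub[1] and iv[1] >= ub[0]]
                seg = cands[0]
                subtype = "intron"
            for _ in range(80):
                pos = self._try_positions(seg[0] + 2, seg[1] - 2,
                                          gene.chrom, gene.strand)
                if pos is None:
                    break
                cat, host, _ = index.locate(gene.chrom, gene.strand, pos)
                if (cat, host) != ("FiveUTR", gene.gene_id):
                    continue
                found = index.upstream_terminus(
                    gene.chrom, gene.strand, pos, exclude=gene.gene_id
                )
                if found is None:
                    continue
                upstream, dist = found
                if not (125 <= dist <= cutoff):
                    continue
                # clamp members so every member stays in the window
                if gene.strand == "+":
                    term = upstream.longest_tx.three_prime_end
                    bounds = (max(seg[0], term + 125), min(seg[1], term + cutoff))
                else:
                    term = upstream.longest_tx.three_prime_end
                    bounds = (max(seg[0], term - cutoff), min(seg[1], term - 125))
                self._plant(gene.chrom, gene.strand, pos, "ThreeUTR",
                            upstream.gene_id, subtype, bounds,
                            reclassified=True)
                found_any = True
                break
            if not found_any:
                raise RuntimeError(
                    f"could not plant reclassification site in {gene.gene_id}"
                )

    def plant_conjunctions(self, index: AnnotationIndex):
        cfg = self.cfg
        rng = self.rng
        normal_hosts: set[str] = set()
        opposite: list[tuple[str, str]] = []  # (pac_id, class)
        for a, b, lo, hi in self.conv_pairs:
            for g in (a, b):
                if rng.random() >= cfg.normal_site_prob:
                    continue
                seg = g.longest_tx.three_utr_segments[0]
                for _ in range(40):
                    pos = self._try_positions(seg[0] + 2, seg[1] - 2,
                                              g.chrom, g.strand)
                    if pos is None:
                        break
                    cat, host, _ = index.locate(g.chrom, g.strand, pos)
                    if (cat, host) != ("ThreeUTR", g.gene_id):
                        continue
                    pid = self._plant(g.chrom, g.strand, pos, "ThreeUTR",
                                      g.gene_id, "exon", seg)
                    normal_hosts.add(g.gene_id)
                    if lo <= pos <= hi:
                        opposite.append((pid, "ThreeUTR"))
                    break
            if rng.random() < cfg.opposite_n3pas_prob:
                # a non-3'UTR site of gene b inside the overlap: the
                # conjunction reaching b's coding region
                tx = b.longest_tx
                segs = [
                    (max(s, lo + 2), min(e, hi - 2))
                    for s, e in tx.cds_exon_segments
                    if min(e, hi - 2) - max(s, lo + 2) >= 40
                ]
                for _ in range(40):
                    if not segs:
                        break
                    seg = segs[int(rng.integers(len(segs)))]
                    pos = self._try_positions(seg[0], seg[1], b.chrom, b.strand)
                    if pos is None:
                        continue
                    cat, host, _ = index.locate(b.chrom, b.strand, pos)
                    if host != b.gene_id or cat not in N3PAS_CATEGORIES:
                        continue
                    pid = self._plant(b.chrom, b.strand, pos, cat,
                                      b.gene_id, None, seg)
                    opposite.append((pid, "n3PAS"))
                    break
        self.conjunction_truth = {
            "n_pairs": len(self.conv_pairs),
            "normal_supported_ends": len(normal_hosts),
            "opposite_pacs": len(opposite),
            "opposite_3utr": sum(1 for _, k in opposite if k == "ThreeUTR"),
            "opposite_n3pas": sum(1 for _, k in opposite if k == "n3PAS"),
        }

    def plant_artifacts(self, index: AnnotationIndex):
        cfg = self.cfg
        rng = self.rng
        singles = [g for g in self.genes
                   if self.gene_archetype[g.gene_id] in ("plain", "long_intron",
                                                         "high_intron")]
        chrom_lengths = {c: cfg.chrom_length for c in self.chrom_names}
        gaps = [
            (c, s, e) for c, s, e in ann.intergenic_regions(
                self.genes, chrom_lengths
            )
            if e - s >= 300 and s > 200 and e < cfg.chrom_length - 200
        ]

        def random_spot():
            if rng.random() < 0.5 and singles:
                g = singles[int(rng.integers(len(singles)))]
                segs = [s for s in g.longest_tx.cds_exon_segments
                        if s[1] - s[0] >= 40]
                if segs:
                    seg = segs[int(rng.integers(len(segs)))]
                    return g.chrom, g.strand, seg[0] + 5, seg[1] - 5
            c, s, e = gaps[int(rng.integers(len(gaps)))]
            strand = "+" if rng.random() < 0.5 else "-"
            return c, strand, s + 140, e - 140

        for i in range(cfg.n_decoys):
            for _ in range(80):
                chrom, strand, lo, hi = random_spot()
                pos = self._try_positions(lo, hi, chrom, strand)
                if pos is None:
                    continue
                self._pac_n += 1
                self._site_n += 1
                self.sites.append(
                    TruthSite(
                        site_id=f"S{self._site_n:05d}",
                        chrom=chrom, strand=strand, pos=pos,
                        tag_count=3 + _nb(rng, cfg.tag_nb_mean,
                                          cfg.tag_nb_dispersion),
                        true_pac=f"TPAC{self._pac_n:04d}",
                        category="decoy", host_gene=None, subtype=None,
                        is_rep=True, is_decoy=True,
                    )
                )
                self.sep.add(chrom, strand, pos)
                run = np.full(cfg.decoy_a_run,
                              ord("A") if strand == "+" else ord("T"),
                              dtype=np.uint8)
                if strand == "+":
                    self._write_seq(chrom, pos - 7, run)
                else:
                    self._write_seq(chrom, pos - 2, run)
                break

        for i in range(cfg.n_low_count):
            for _ in range(80):
                chrom, strand, lo, hi = random_spot()
                pos = self._try_positions(lo, hi, chrom, strand)
                if pos is None:
                    continue
                self._pac_n += 1
                self._site_n += 1
                self.sites.append(
                    TruthSite(
                        site_id=f"S{self._site_n:05d}",
                        chrom=chrom, strand=strand, pos=pos,
                        tag_count=int(rng.integers(1, 3)),
                        true_pac=f"TPAC{self._pac_n:04d}",
                        category="low_count", host_gene=None, subtype=None,
                        is_rep=True, is_low_count=True,
                    )
                )
                self.sep.add(chrom, strand, pos)
                break

    # -- flank signal and the exact priming property ------------------------

    def write_elements(self):
        """A-rich element over -20..-10 of most real sites (oriented)."""
        cfg = self.cfg
        rng = self.rng
        probs = np.array([0.5, 0.1, 0.1, 0.3])
        for s in self.sites:
            if s.is_decoy or rng.random() >= cfg.a_element_prob:
                continue
            elem = _BASE_CODES[rng.choice(4, size=11, p=probs)]
            if s.strand == "+":
                self._write_seq(s.chrom, s.pos - 20, elem)
            else:
                # reverse-complement so the oriented strand sees the same
                # composition
                trans = {ord("A"): ord("T"), ord("C"): ord("G"),
                         ord("G"): ord("C"), ord("T"): ord("A")}
                rc = np.array([trans[int(b)] for b in elem[::-1]],
                              dtype=np.uint8)
                self._write_seq(s.chrom, s.pos + 10, rc)

    def enforce_priming_property(self):
        """Repair non-decoy windows until none carries an A-run >= 8,
        then assert the decoy/non-decoy split is exact."""
        for _ in range(6):
            dirty = False
            for s in self.sites:
                if s.is_decoy:
                    continue
                win = self._oriented_window(s.chrom, s.strand, s.pos)
                while max_base_run(win, "A") >= PRIMING_A_RUN:
                    dirty = True
                    k = win.find("A" * PRIMING_A_RUN) + PRIMING_A_RUN // 2
                    if s.strand == "+":
                        gpos = s.pos - 10 + k
                        self._write_seq(s.chrom, gpos,
                                        np.array([ord("C")], dtype=np.uint8))
                    else:
                        gpos = s.pos + 10 - k
                        self._write_seq(s.chrom, gpos,
                                        np.array([ord("G")], dtype=np.uint8))
                    win = self._oriented_window(s.chrom, s.strand, s.pos)
            if not dirty:
                break
        for s in self.sites:
            win = self._oriented_window(s.chrom, s.strand, s.pos)
            run = max_base_run(win, "A")
            if s.is_decoy and run < PRIMING_A_RUN:
                raise RuntimeError(f"decoy {s.site_id} lost its A-run")
            if not s.is_decoy and run >= PRIMING_A_RUN:
                raise RuntimeError(f"site {s.site_id} window not repaired")

    # -- transposable elements ----------------------------------------------

    def place_tes(self):
        cfg = self.cfg
        rng = self.rng
        fam_cycle = ["Helitron"] * 4 + ["DNA"] * 3 + ["LINE"] * 2 + \
            ["SINE"] + ["LTR"]
        sense_targets = [
            s for s in self.sites
            if s.is_rep and not s.is_decoy and not s.is_low_count
            and s.category in ("ThreeUTR", "FiveUTR", "CdsExon", "CdsIntron")
            and not s.reclassified and s.host_gene is not None
        ]
        order = rng.permutation(len(sense_targets))
        te_n = 0
        placed = 0
        for idx in order:
            if placed >= cfg.n_te_associated:
                break
            s = sense_targets[int(idx)]
            ok = False
            for _ in range(50):
                d = int(rng.integers(0, cfg.te_cutoff + 1))
                te_len = int(rng.integers(cfg.te_len_min, cfg.te_len_max + 1))
                left = rng.random() < 0.5
                if d == 0:
                    start = s.pos - int(rng.integers(5, te_len - 5))
                    end = start + te_len - 1
                elif left:
                    end = s.pos - d
                    start = end - te_len + 1
                else:
                    start = s.pos + d
                    end = start + te_len - 1
                if start < 200 or end > cfg.chrom_length - 200:
                    continue
                reps = self.sep.positions(s.chrom)
                bad = False
                for r in reps:
                    if r == s.pos:
                        continue
                    dr = 0 if start <= r <= end else min(
                        abs(r - start), abs(r - end)
                    )
                    if dr <= cfg.te_cutoff + 5:
                        bad = True
                        break
                if bad:
                    continue
                te_n += 1
                placed += 1
                te_id = f"TE{te_n:04d}"
                fam = fam_cycle[(placed - 1) % len(fam_cycle)]
                self.tes.append(TeRecord(te_id, s.chrom, start, end, fam))
                real_d = 0 if start <= s.pos <= end else min(
                    abs(s.pos - start), abs(s.pos - end)
                )
                self.te_truth.append(
                    {"te_id": te_id, "target_pac": s.true_pac,
                     "distance": real_d, "family": fam,
                     "category_class": (
                         "n3PAS" if s.category in N3PAS_CATEGORIES
                         else "ThreeUTR")}
                )
                ok = True
                break
            if not ok:
                continue

        chrom_lengths = {c: cfg.chrom_length for c in self.chrom_names}
        gaps = [
            (c, s, e) for c, s, e in ann.intergenic_regions(
                self.genes, chrom_lengths
            )
            if e - s >= 400
        ]
        families = list(ann.TE_FAMILIES)
        for _ in range(cfg.n_te_background):
            for _ in range(60):
                c, s, e = gaps[int(rng.integers(len(gaps)))]
                te_len = int(rng.integers(cfg.te_len_min, cfg.te_len_max + 1))
                start = int(rng.integers(s + 50, e - 50 - te_len))
                end = start + te_len - 1
                reps = self.sep.positions(c)
                bad = any(
                    (start <= r <= end) or min(abs(r - start), abs(r - end))
                    <= cfg.te_cutoff + 20
                    for r in reps
                )
                if bad:
                    continue
                te_n += 1
                self.tes.append(
                    TeRecord(f"TE{te_n:04d}", c, start, end,
                             families[int(rng.integers(len(families)))])
                )
                break
        self.tes.sort(key=lambda t: (t.chrom, t.start, t.te_id))

    # -- driver --------------------------------------------------------------

    def run(self) -> Fixture:
        self.place_genes()
        index = AnnotationIndex(self.genes)
        self.plant_generic(index)
        self.plant_reclass(index)
        self.plant_conjunctions(index)
        self.plant_artifacts(index)
        self.write_elements()
        self.enforce_priming_property()
        self.place_tes()
        # finalize per-gene PAC-group truth from what was actually planted
        has3, hasn3 = set(), set()
        for s in self.sites:
            if s.is_decoy or s.is_low_count or not s.is_rep:
                continue
            if s.category == "ThreeUTR" and s.host_gene:
                has3.add(s.host_gene)
            elif s.category in N3PAS_CATEGORIES and s.host_gene:
                hasn3.add(s.host_gene)
        for g in self.genes:
            gid = g.gene_id
            if gid in has3 and gid in hasn3:
                grp = "Both"
            elif gid in has3:
                grp = "Only3UTR"
            elif gid in hasn3:
                grp = "OnlyNon3UTR"
            else:
                grp = "NoPAC"
            self.gene_truth[gid]["pac_group"] = grp
        genome = {c: arr.tobytes().decode() for c, arr in self.seq.items()}
        return Fixture(
            config=self.cfg,
            genome=genome,
            genes=self.genes,
            gene_truth=self.gene_truth,
            tes=self.tes,
            te_truth=self.te_truth,
            sites=sorted(self.sites,
                         key=lambda s: (s.chrom, s.pos, s.strand)),
            pair_truth=self.pair_truth,
            conjunction_truth=self.conjunction_truth,
        )


def generate(config: ScenarioConfig | None = None) -> Fixture:
    """Generate one fixture bundle. Same config (incl. seed) -> same
    fixture, byte for byte once written."""
    return _Generator(config or ScenarioConfig()).run()


def parameter_sweep(base: ScenarioConfig, axis: str, values) -> list[Fixture]:
    """One fixture per value of ``axis``, with seeds derived
    deterministically from the base seed and the value index."""
    if axis not in {f.name for f in dataclasses.fields(ScenarioConfig)}:
        raise ValueError(f"unknown config field {axis!r}")
    out = []
    for i, v in enumerate(values):
        seed = (base.seed + 104729 * i) % (2**31 - 1)
        out.append(generate(replace(base, **{axis: v, "seed": seed})))
    return out
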