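# n3pas

Genome-wide identification and characterization of **non-3'UTR
poly(A) site clusters** from strand-aware poly(A)-tag alignments and a
genome annotation.

Tag-based 3'-end sequencing (PAT-seq, direct RNA sequencing) anchors
each read at a cleavage-and-polyadenylation position. Most of these
positions sit in annotated 3'UTRs, but a consistent minority falls in
5'UTRs, CDS exons and CDS introns (non-3'UTR poly(A) sites, *n3PAS*),
antisense to genes, or in intergenic space. This package is for
genomicists who have such alignments and want, from a GFF3 annotation
and a genome FASTA:

* filtered single-base poly(A) sites — internal-priming artifacts
  removed by scanning the −10..+5 window for ≥ 8 consecutive genomic
  A's, low-support sites (< 3 tags) discarded;
* poly(A) site clusters (PACs) — single-linkage chaining of sites
  within 24 nt, each summarized by the most-supported (representative)
  site;
* a six-way classification of every PAC against the longest transcript
  of each protein-coding gene, its terminus extended 120 nt:
  `FiveUTR | CdsExon | CdsIntron | ThreeUTR | Intergenic | Antisense`,
  with a 400 nt rescue that relabels 5'UTR calls lying just past an
  upstream gene's terminus as that gene's 3'UTR read-through;
* host-gene architecture labels (spliced / ambiguous / extreme-short
  5'UTRs with precedence, long introns: > 800 nt or > 1/3 of the gene
  span, intron counts, Only3UTR / Both / OnlyNon3UTR grouping);
* the convergent-gene-pair analysis ("normal" vs "opposite" PACs at
  350–1000 nt conjunctions), transposable-element association within
  40 nt, and −100..+100 nucleotide-composition profiles;
* chi-square feature-frequency and Welch intron-length statistics.

A fully self-contained synthetic-data module generates genome + GFF3 +
TE + tag fixtures with machine-readable ground truth for every stage,
so the entire chain is testable without any external data. See
`docs/methods.md` for the model, parameter rationale and limitations.

## Worked example

```python
from n3pas import ScenarioConfig, generate, run_all
from n3pas.extraction import PolyASite

fx = generate(ScenarioConfig(seed=42))          # synthetic study scenario
sites = [PolyASite(*rec) for rec in fx.site_records()]
res = run_all(genes=fx.genes, genome=fx.genome, sites=sites, tes=fx.tes)

print(res["category_tally"])
il = res["intron_length"]
print(f"intron length with/without PAC: "
      f"{il['mean_with']:.1f} / {il['mean_without']:.1f} nt "
      f"(Welch P = {il['p_value']:.2e})")
print("conjunctions:", {k: v for k, v in res["conjunction"].items()
                        if k != "per_pair"})
```

prints

```
            n_pacs  n_tags
category
FiveUTR         25     293
CdsExon         32     528
CdsIntron       50     777
ThreeUTR       167    2432
Intergenic      25     347
Antisense       25     423
n3PAS          107    1598
intron length with/without PAC: 674.1 / 166.4 nt (Welch P = 1.01e-06)
conjunctions: {'n_pairs': 10, 'n_gene_ends': 20, 'normal_supported_ends': 15,
               'opposite_pacs': 22, 'opposite_3utr': 15, 'opposite_n3pas': 7}
```

Reading this: 324 PACs were called on the ~200-gene scenario; the
`n3PAS` row aggregates the three non-3'UTR categories (107 clusters,
1598 supporting tags). Introns that contain a PAC average 674 nt
against 166 nt for introns that do not — the long-intron preference,
strongly significant by Welch's t-test. Of the ten convergent gene
pairs with a 350–1000 nt overlap, 15 of 20 gene ends have a supporting
("normal") 3'UTR cluster, and 22 clusters inside the overlaps are
"opposite" PACs attributable to the partner gene, 7 of them non-3'UTR
calls where the conjunction reaches the partner's coding region.

The same analysis runs from files (any GFF3 + FASTA + BED6 of sites +
TE table, e.g. a real genome annotation):

```sh
n3pas simulate --out fixture/ --seed 42        # or bring your own files
n3pas run-all --gff fixture/genes.gff3 --fasta fixture/genome.fa \
      --tags fixture/tags.bed --te fixture/tes.tsv --out report/
```

`report/` then contains the PAC table, classified calls, category
summary, gene labels, overlap census, conjunction table, TE
associations and family tally, per-category composition profiles, and
`report.json` with parameters and per-stage record counts. Reruns with
the same inputs and seed are byte-identical.

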