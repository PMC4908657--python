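# Methods

## Problem and model

Poly(A)-tag sequencing (PAT-seq) and direct RNA sequencing anchor each
read at the cleavage-and-polyadenylation position of a transcript, so
every aligned tag is one observation of a single-base poly(A) site.
Most sites fall in annotated 3'UTRs, but a reproducible minority lies
in 5'UTRs, CDS exons and CDS introns (collectively *non-3'UTR* sites,
n3PAS), on the antisense strand, or in intergenic space. This package
implements the full chain from tag alignments to a characterization of
those non-3'UTR sites and of the gene architectures that accompany
them.

The processing model is:

1. **Collapse.** Tags sharing (chromosome, strand, position) become one
   site with a tag count.
2. **Internal-priming filter.** Oligo(dT) priming on genomically
   encoded A stretches creates false sites. The 16 nt window from
   −10 to +5 around the site (position 0 = the cleavage base, read on
   the transcription strand, reverse-complemented for − sites) is
   scanned; a run of ≥ 8 consecutive A drops the site. The window is
   truncated at chromosome edges; a window entirely off the chromosome
   is an error.
3. **Support filter.** Sites with fewer than 3 tags are discarded
   (inclusive threshold: 3 tags are kept).
4. **Clustering.** Cleavage microheterogeneity scatters sites over a
   few dozen nt around each functional poly(A) site. Sites on one
   (chromosome, strand) are chained by single linkage: consecutive
   position-sorted sites join one poly(A) site cluster (PAC) when their
   gap is ≤ 24 nt. The representative site of a PAC is the member with
   the most tags; ties go to the 3'-most member in the transcription
   direction.
5. **Classification.** Against protein-coding gene models (longest
   transcript only, organelle chromosomes excluded, transcript terminus
   extended 120 nt downstream to absorb unannotated 3'UTR ends), the
   representative position decides the category: 5'UTR segment →
   FiveUTR; CDS exon → CdsExon; intron between the CDS bounds →
   CdsIntron; 3'UTR segment or the 120 nt extension → ThreeUTR. A
   position outside every same-strand transcript but inside an
   opposite-strand extended gene span is Antisense; everything else is
   Intergenic. Sense beats antisense beats intergenic.
6. **400 nt rescue.** A FiveUTR call whose representative position lies
   1–400 nt downstream of the 3' terminus of the nearest upstream
   same-strand gene is relabeled as that gene's ThreeUTR call
   (read-through whose cluster was attributed to the next gene's
   5'UTR); the original exon/intron subtype is kept so the rescued set
   can be reported split by subtype.
7. **Host-gene features.** Genes are labeled *spliced 5'UTR* (any
   isoform has an intron wholly or partly within its 5'UTR extent),
   else *ambiguous 5'UTR* (≥ 2 isoforms whose 5'UTRs differ in genomic
   start or end), else *extreme short 5'UTR* (longest-transcript 5'UTR
   ≤ 10 nt; a gene with no annotated 5'UTR counts as length 0 and is
   logged), else none — precedence spliced > ambiguous > extreme short.
   A gene is *long-intron* when any isoform has an intron > 800 nt or
   > 1/3 of the gene span (both strict). Genes group by sense PAC
   content into Only3UTR / Both / OnlyNon3UTR / NoPAC.
8. **Convergent conjunctions.** Overlapping gene pairs (annotated,
   unextended spans) are classed convergent / divergent / same by
   strand and which gene lies left. Convergent pairs with an overlap of
   350–1000 nt (inclusive) form the conjunction set; a gene end is
   "normal"-supported when a ThreeUTR call hosted by that gene exists,
   and calls inside the overlap are "opposite" PACs of the partner
   gene, split by whether the host carries them as ThreeUTR or as
   non-3'UTR calls.
9. **TE association.** A PAC associates with a transposable element
   when its representative site is inside the TE (distance 0) or within
   40 nt of the nearest TE edge (inclusive by default; the comparator
   is a flag). Strand is ignored. The family tally counts each
   sense-genic PAC once, under its nearest TE.
10. **Profiles and statistics.** Per-category single-nucleotide
    composition over −100..+100 around representative sites on the
    transcription strand; Pearson chi-square (no continuity correction
    by default) for feature-frequency comparisons; Welch
    unequal-variance t-test for intron-length comparisons. Significance
    is read at P = 0.05.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| priming window | −10..+5 | nt | region an oligo(dT) primer can anneal over |
| priming A-run | ≥ 8 | nt | canonical internal-priming criterion |
| min tag support | 3 | tags | inclusive; separates sites from sequencing noise |
| cluster gap | 24 | nt | microheterogeneity convention for this genome; CLI flag |
| 3' extension | 120 | nt | absorbs systematically under-annotated 3'UTR ends |
| reclassification cutoff | 400 | nt | read-through reach past an upstream terminus |
| long intron | > 800 or > span/3 | nt | extreme versus typical (~100 nt median) intron length |
| short 5'UTR | ≤ 10 | nt | effectively headless transcript |
| conjunction overlap | 350–1000 | nt | overlaps deep enough to cross both 3'UTRs but still gene tails |
| TE distance | ≤ 40 | nt | proximity criterion; comparator configurable |
| profile flank | 100 | nt | covers the known upstream/downstream signal elements |

"Longest transcript" is measured as genomic span (end − start + 1), the
genome-browser sense of longest, with ties broken by lexicographically
smallest transcript id so selection is input-order independent.
Introns wholly 5' of the CDS classify as FiveUTR (intron subtype) and
wholly 3' of the CDS as ThreeUTR, so CdsIntron means strictly introns
between the CDS bounds. When overlapping same-strand genes both
contain a position, the host is the gene holding it in the most-3'
category (ThreeUTR > CdsIntron > CdsExon > FiveUTR), then the nearer 3'
terminus — the reading that treats shared positions as gene termini.

## Synthetic data

`n3pas.simulate` builds fully self-contained fixtures: genome FASTA,
GFF3, TE table, tag BED, and per-site / per-gene / per-pair / per-TE
ground truth. The default scenario is ~200 genes on two 450 kb
chromosomes with ~320 true PACs and roughly 5000 tags; gene archetypes
(plain, spliced / ambiguous / extreme-short 5'UTR, long-intron,
high-intron-count, convergent / divergent / tandem pairs) are drawn in
fixed proportions, and sites are planted per category, including the
extension zone, antisense and intergenic space, plus mis-annotated
5'UTR cases placed 125–400 nt past an upstream terminus.

Specifics worth knowing:

* **Exact priming property.** Background sequence is i.i.d. uniform
  ACGT with A-runs and T-runs ≥ 8 broken during generation; decoy sites
  get a written 10 nt A-run (T-run for − sites) inside their window,
  and after all signal elements are written every non-decoy site window
  is re-scanned and repaired. The decoy/kept split under the filter is
  therefore exact, not probabilistic.
* **Tag depth.** Member tag counts are negative binomial (mean 8,
  dispersion 2), shifted so planted sites survive the support filter;
  separate low-support sites (1–2 tags) exercise that filter.
* **Microheterogeneity.** Extra member sites per true PAC
  (1 + Poisson(0.5)) at discretized-Laplace offsets (scale 4, truncated
  ± 20), constrained to stay chained within the clustering gap and
  inside the same genic segment as the representative. True PACs
  therefore never split or merge under default clustering, which is
  what makes the planted tallies exactly recoverable; jitter wider than
  the chain constraint is deliberately not emitted.
* **Long-intron effect.** CDS-intron sites pick their intron with
  probability proportional to length², so introns containing sites are
  systematically longer — the effect the intron-length comparison is
  expected to recover.
* **Controlled TE geometry.** Associated TEs are placed 0–40 nt from
  chosen sense-genic sites after checking that no other representative
  site falls within the cutoff (plus margin) of the element; background
  TEs keep > 60 nt away from every site. Each target therefore yields
  exactly one association.
* Representative sites keep ≥ 70 nt same-strand and ≥ 50 nt
  any-strand separation so clusters, priming windows and decoy edits
  cannot interact.

What the fixtures do **not** emulate: realistic base composition
(GC skew, isochores), sequencing error, alignment ambiguity or
multimapping, isoform-level expression structure beyond one or two
annotated isoforms, chained multi-gene overlaps, nested TEs, or the
chemistry differences between tag-based and direct-RNA protocols.
Passing tests therefore demonstrate correctness of the genomic logic
and statistics under clean geometry, not robustness to alignment or
library artifacts in real data.

## Numerical and degenerate-input choices

* All coordinates are 1-based inclusive (GFF3 convention) end to end;
  BED input/output converts at the boundary.
* UTR segments are taken from explicit UTR features when present, else
  reconstructed as exon minus CDS; CDS intervals are clipped to exons
  defensively. Transcripts without exons are skipped with a warning;
  transcripts without CDS classify their exons as CdsExon.
* The 120 nt extension is clipped at chromosome ends (warning), and a
  gene extending past the chromosome end is clipped in the intergenic
  complement.
* Welch's t-test is used rather than the pooled t-test because
  intron-length variances differ grossly between groups; with two
  zero-variance groups of equal mean, t = 0 and P = 1 by convention. A
  group with fewer than two introns reports means with P unavailable.
* Chi-square defaults to no continuity correction (the R default for
  2×2 applies Yates; both are exposed). Expected cells < 5 warn.
* The composition profile excludes N bases from the per-position
  denominator and reports them separately; sites nearer than one flank
  to a chromosome edge are skipped and counted.
* Report output contains no timestamps, so a rerun with the same
  inputs, parameters and seed is byte-identical.
* Clustering with gap 0 merges only exact duplicate positions (which
  collapse earlier), so it yields singletons; the tie-break for equal
  representative counts picks the 3'-most member (downstream-most
  cleavage), a deterministic convention.

## Scale

The default test scenario (≈ 200 genes, ≈ 5000 tags) runs the whole
pipeline in well under a second on one CPU; the replicate study in the
test suite (100 regenerated scenarios) runs in seconds. Problem sizes
in the acceptance script match the default scenario. The same code
paths accept a real genome annotation (GFF3 + FASTA + TE table) through
the CLI; the TE scan is linear per chromosome and adequate at desk
scale, and would be the first thing to index for genome-scale TE
catalogues.

## Known limitations

* Classification is decided by the representative site, not the PAC
  span; a cluster straddling a boundary is assigned wholly to its
  representative's segment.
* Sense classification is strictly against the longest transcript (plus
  extension): a position inside a gene's span but outside its longest
  transcript — possible when another isoform extends further — falls
  through to antisense/intergenic rather than receiving a sense call.
* The ambiguous-5'UTR label triggers on any coordinate difference
  between isoform 5'UTRs, including 1 nt; no fuzz threshold is applied.
* Orientation of an overlapping pair with identical spans on opposite
  strands is resolved lexicographically (convergent); such pairs are
  degenerate and absent from real annotations.
* No multiple-testing correction is applied across feature tests.
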