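"""End-to-end orchestration and the consolidated report.

``run_all`` executes every stage in order — site collapse, internal-
priming filter, tag-support filter, clustering, six-way classification
with the 400 nt rescue, gene labeling, overlap and TE association
analyses, composition profiles and the statistical comparisons — and
writes one report directory of TSV tables plus a JSON summary. The
report body carries no timestamps, so identical inputs and parameters
reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .annotation import load_annotation, load_tes
from .classification import (
    AnnotationIndex,
    N3PAS_CATEGORIES,
    classify_pacs,
    reclassify_5utr,
    tally_categories,
)
from .extraction import (
    cluster_sites,
    filter_internal_priming,
    quality_filter,
    read_site_bed,
    write_pac_table,
)
from .features import (
    intron_count_curve,
    intron_length_comparison,
    label_genes,
)
from .overlap import (
    find_overlap_pairs,
    orientation_census,
    select_conjunction_pairs,
    tally_conjunction_pacs,
)
from .profiles import composition_profile
from .stats import feature_frequency_test
from .te import associate_tes, family_tally


@dataclass(frozen=True)
class PipelineParams:
    cluster_gap: int = 24
    min_tags: int = 3
    reclass_cutoff: int = 400
    te_cutoff: int = 40
    te_inclusive: bool = True
    flank: int = 100
    chi2_correction: bool = False
    organelle_exclude: tuple[str, ...] = ("ChrC", "ChrM")


def _write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_all(
    gff3: str | None = None,
    genome=None,
    tag_bed: str | None = None,
    te_path: str | None = None,
    out_dir: str | None = None,
    params: PipelineParams | None = None,
    seed: int = 0,
    genes=None,
    sites=None,
    tes=None,
) -> dict:
    """Run the full analysis and (optionally) write the report.

    Inputs may be file paths (``gff3``, ``tag_bed``, ``te_path``) or
    pre-built objects (``genes``, ``sites``, ``tes``); ``genome`` is a
    pyfaidx handle or a chrom -> sequence mapping. Returns a dict of
    all stage outputs.
    """
    params = params or PipelineParams()
    if genes is None:
        if gff3 is None:
            raise ValueError("either gff3 or genes is required")
        genes = load_annotation(gff3, organelle_exclude=params.organelle_exclude)
    if sites is None:
        if tag_bed is None:
            raise ValueError("either tag_bed or sites is required")
        sites = read_site_bed(tag_bed)
    if tes is None and te_path is not None:
        tes = load_tes(te_path)
    tes = tes or []

    n_input_sites = len(sites)
    if genome is not None:
        sites, priming_dropped = filter_internal_priming(sites, genome)
    else:
        priming_dropped = []
    sites = quality_filter(sites, min_tags=params.min_tags)
    pacs = cluster_sites(sites, cluster_gap=params.cluster_gap)

    index = AnnotationIndex(genes)
    calls = classify_pacs(pacs, index)
    calls = reclassify_5utr(calls, index, cutoff=params.reclass_cutoff)
    category_tally = tally_categories(calls)
    n_reclass = sum(1 for c in calls if c.reclassified)
    reclass_subtypes = {
        "exon": sum(1 for c in calls if c.reclassified and c.subtype == "exon"),
        "intron": sum(
            1 for c in calls if c.reclassified and c.subtype == "intron"
        ),
    }

    labels = label_genes(genes, calls)
    curve = intron_count_curve(labels, calls)
    intron_cmp = intron_length_comparison(genes, calls)

    # feature frequencies: genome-wide vs hosts of non-3'UTR calls
    n3_hosts = {
        c.host_gene for c in calls if c.category in N3PAS_CATEGORIES
    }
    host_labels = [l for l in labels if l.gene_id in n3_hosts]
    freq_tests = {}
    for feat, pred in (
        ("atypical_5utr", lambda l: l.atypical5utr != "none"),
        ("long_intron", lambda l: l.long_intron),
    ):
        gv = (sum(pred(l) for l in labels), sum(not pred(l) for l in labels))
        hv = (
            sum(pred(l) for l in host_labels),
            sum(not pred(l) for l in host_labels),
        )
        if gv[0] + gv[1] > 0 and hv[0] + hv[1] > 0 and 0 not in (
            gv[0] + hv[0], gv[1] + hv[1]
        ):
            freq_tests[feat] = feature_frequency_test(
                feat, gv, hv, correction=params.chi2_correction
            )

    pairs = find_overlap_pairs(genes)
    census = orientation_census(pairs)
    selected = select_conjunction_pairs(pairs)
    conjunction = tally_conjunction_pacs(selected, calls)

    assocs = associate_tes(
        calls, tes, cutoff=params.te_cutoff, inclusive=params.te_inclusive
    )
    te_tally = family_tally(assocs, calls)

    profiles = (
        composition_profile(calls, genome, flank=params.flank)
        if genome is not None
        else {}
    )

    results = {
        "params": params,
        "seed": seed,
        "n_input_sites": n_input_sites,
        "n_priming_dropped": len(priming_dropped),
        "priming_dropped": priming_dropped,
        "n_quality_sites": len(sites),
        "sites": sites,
        "pacs": pacs,
        "calls": calls,
        "category_tally": category_tally,
        "n_reclassified": n_reclass,
        "reclass_subtypes": reclass_subtypes,
        "labels": labels,
        "intron_curve": curve,
        "intron_length": intron_cmp,
        "frequency_tests": freq_tests,
        "overlap_pairs": pairs,
        "orientation_census": census,
        "conjunction_pairs": selected,
        "conjunction": conjunction,
        "te_associations": assocs,
        "te_tally": te_tally,
        "profiles": profiles,
    }
    if out_dir is not None:
        write_report(results, out_dir)
    return results


def write_report(results: dict, out_dir: str) -> None:
    """Write all report tables. Deterministic: no timestamps."""
    os.makedirs(out_dir, exist_ok=True)
    write_pac_table(results["pacs"], os.path.join(out_dir, "pacs.tsv"))

    rows = []
    for c in results["calls"]:
        rows.append(
            {
                "pac_id": c.pac.pac_id,
                "chrom": c.pac.chrom,
                "strand": c.pac.strand,
                "rep_pos": c.pac.rep_pos,
                "total_tags": c.pac.total_tags,
                "category": c.category,
                "host_gene": c.host_gene or ".",
                "subtype": c.subtype or ".",
                "reclassified": int(c.reclassified),
            }
        )
    _write_tsv(pd.DataFrame(rows), os.path.join(out_dir, "classified_pacs.tsv"))
    _write_tsv(
        results["category_tally"],
        os.path.join(out_dir, "category_summary.tsv"),
        index=True,
    )
    _write_tsv(
        pd.DataFrame([dataclasses.asdict(l) for l in results["labels"]]),
        os.path.join(out_dir, "gene_labels.tsv"),
    )
    _write_tsv(results["intron_curve"], os.path.join(out_dir, "intron_curve.tsv"))
    _write_tsv(
        results["orientation_census"],
        os.path.join(out_dir, "overlap_census.tsv"),
        index=True,
    )
    _write_tsv(
        results["conjunction"]["per_pair"],
        os.path.join(out_dir, "conjunction_pairs.tsv"),
    )
    _write_tsv(
        pd.DataFrame([dataclasses.asdict(a) for a in results["te_associations"]]),
        os.path.join(out_dir, "te_associations.tsv"),
    )
    _write_tsv(
        results["te_tally"], os.path.join(out_dir, "te_family_tally.tsv"),
        index=True,
    )
    prof_dir = os.path.join(out_dir, "profiles")
    os.makedirs(prof_dir, exist_ok=True)
    for cat, df in results["profiles"].items():
        _write_tsv(df, os.path.join(prof_dir, f"{cat}.tsv"))

    summary = {
        "tool_version": __version__,
        "seed": results["seed"],
        "params": dataclasses.asdict(results["params"]),
        "record_counts": {
            "input_sites": results["n_input_sites"],
            "internal_priming_dropped": results["n_priming_dropped"],
            "quality_sites": results["n_quality_sites"],
            "pacs": len(results["pacs"]),
            "reclassified_5utr": results["n_reclassified"],
            "reclassified_subtypes": results["reclass_subtypes"],
            "overlap_pairs": len(results["overlap_pairs"]),
            "conjunction_pairs": len(results["conjunction_pairs"]),
            "te_associations": len(results["te_associations"]),
        },
        "category_tally": {
            k: {"n_pacs": int(v["n_pacs"]), "n_tags": int(v["n_tags"])}
            for k, v in results["category_tally"].iterrows()
        },
        "intron_length": {
            k: (None if v != v else round(float(v), 4))
            for k, v in results["intron_length"].items()
        },
        "frequency_tests": {
            k: {
                "genome_rate": round(v.genome_rate, 6),
                "host_rates": {n: round(r, 6) for n, r in v.host_rates.items()},
                "chi_square": round(v.chi_square, 6),
                "p_value": float(f"{v.p_value:.6g}"),
            }
            for k, v in results["frequency_tests"].items()
        },
        "conjunction": {
            k: int(v)
            for k, v in results["conjunction"].items()
            if k != "per_pair"
        },
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
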