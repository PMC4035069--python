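"""End-to-end orchestration: simulate -> clean -> annotate -> quantify ->
diffexpr -> novel -> targets -> enrich -> qpcr, with a JSON run manifest
recording the config snapshot and a digest of every output file."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import annotate, diffexpr, enrichment, novel_mirna, preprocess, qpcr, quantify, targets
from . import io
from .references import ReferenceBundle
from .synthetic_data import SimulationConfig, build_reference_set, simulate_ct_table, simulate_libraries

logger = logging.getLogger("ovamir")


def _log(stage: str, message: str) -> None:
    logger.info("[%s] %s", stage, message)


def run_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run the whole study on synthetic data; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        io.write_tsv(path, df)
        outputs[name] = path

    # --- simulate ---------------------------------------------------------
    _log("simulate", f"seed={config.seed} depths={config.library_depths}")
    refs = build_reference_set(config)
    refs.bundle.save(out / "references")
    for f in sorted((out / "references").iterdir()):
        outputs[f"references/{f.name}"] = f
    lib1_fq, lib2_fq = out / "lib1.fastq", out / "lib2.fastq"
    truth = simulate_libraries(config, refs, lib1_fq, lib2_fq)
    truth.save(out / "truth")
    outputs["lib1.fastq"] = lib1_fq
    outputs["lib2.fastq"] = lib2_fq
    ct_table = simulate_ct_table(config, truth)
    emit("ct_table.tsv", ct_table)
    config.to_yaml(out / "config.yaml")
    outputs["config.yaml"] = out / "config.yaml"

    # --- clean ------------------------------------------------------------
    tags1, report1 = preprocess.clean_reads(lib1_fq, config.adapter3, config.adapter5)
    tags2, report2 = preprocess.clean_reads(lib2_fq, config.adapter3, config.adapter5)
    _log("clean", f"clean reads: {report1.clean_reads} / {report2.clean_reads}")
    rep = report1.to_frame().merge(report2.to_frame(), on="type", suffixes=("_lib1", "_lib2"))
    emit("filter_report.tsv", rep)
    hist_rows = []
    for lib, tags in (("lib1", tags1), ("lib2", tags2)):
        for length, (count, frac) in preprocess.length_distribution(tags).items():
            hist_rows.append({"library": lib, "length": length, "count": count,
                              "fraction": round(frac, 6)})
    emit("length_distribution.tsv", pd.DataFrame(
        hist_rows, columns=["library", "length", "count", "fraction"]))
    tag_table = preprocess.collapse_tags(tags1, tags2)
    emit("unique_tags.tsv", tag_table)

    # --- annotate ---------------------------------------------------------
    annotated = annotate.annotate_table(tag_table, refs.bundle)
    emit("annotated_tags.tsv", annotated)
    emit("composition.tsv", annotate.summarize_composition(annotated))
    _log("annotate", f"{len(annotated)} unique tags categorised")

    # --- quantify ---------------------------------------------------------
    records, _unassigned = quantify.assign_tags_to_mirnas(annotated, refs.bundle.mature)
    records = quantify.call_expression_sets(records) if len(records) else records
    emit("expression.tsv", records)
    n1, n2 = max(report1.clean_reads, 1), max(report2.clean_reads, 1)
    if len(records):
        top = quantify.top_specific_report(records, n1, n2)
        emit("top_specific_lib1.tsv", top["lib1"])
        emit("top_specific_lib2.tsv", top["lib2"])
    _log("quantify", f"{len(records)} miRNAs detected")

    # --- diffexpr ---------------------------------------------------------
    de = diffexpr.de_table(records, n1, n2) if len(records) else pd.DataFrame()
    emit("de_table.tsv", de)
    if len(de):
        n_sig = int((de["sig_label"] != "None").sum())
        _log("diffexpr", f"{n_sig} significant of {len(de)}")
        if n_sig >= 2:
            tree = diffexpr.cluster_de(de)
            (out / "de_clusters.nwk").write_text(tree.newick() + "\n")
            outputs["de_clusters.nwk"] = out / "de_clusters.nwk"

    # --- novel ------------------------------------------------------------
    unann = annotated[annotated["category"] == "unann"]
    hits = annotate.map_to_genome(unann["tag"], refs.bundle.genome)
    tag_hits = [(r["tag"], int(r["count_lib1"]), int(r["count_lib2"]), hits[r["tag"]])
                for _, r in unann.iterrows()]
    windows = novel_mirna.extract_candidates(tag_hits, refs.bundle.genome)
    candidates = novel_mirna.merge_candidates_by_locus(
        novel_mirna.call_novel(windows, refs.bundle.features))
    emit("novel_candidates.tsv", novel_mirna.candidates_to_table(candidates))
    if candidates:
        io.write_bed(out / "novel_candidates.bed", novel_mirna.candidates_to_bed(candidates))
        outputs["novel_candidates.bed"] = out / "novel_candidates.bed"
        with open(out / "novel_structures.txt", "w") as fh:
            for i, c in enumerate(candidates):
                fh.write(f">novel-{i + 1} {c.chrom}:{c.start}-{c.end}({c.strand}) "
                         f"energy={c.energy_score:.2f}\n{c.precursor}\n{c.structure}\n")
        outputs["novel_structures.txt"] = out / "novel_structures.txt"
    _log("novel", f"{len(candidates)} hairpin candidates")

    # --- targets ----------------------------------------------------------
    mirna_seqs = {r["mirna_id"]: r["sequence"] for _, r in records.iterrows()} \
        if len(records) else {}
    for i, c in enumerate(candidates):
        mirna_seqs[f"novel-{i + 1}"] = c.mature_seq
    hit_list, tallies = targets.scan_targets(mirna_seqs, refs.bundle.utrs)
    emit("target_hits.tsv", targets.hits_to_frame(hit_list))
    emit("target_tallies.tsv", tallies)
    target_genes = targets.target_gene_set(hit_list)
    _log("targets", f"{len(hit_list)} sites in {len(target_genes)} genes")

    # --- enrich -----------------------------------------------------------
    go_parts = []
    for ont in enrichment.GO_ONTOLOGIES:
        sub = refs.bundle.go_map[refs.bundle.go_map["term"].str.startswith(ont + ":")]
        go_parts.append(enrichment.enrichment_table(target_genes, sub, ontology=ont))
    go = enrichment.correct_go(pd.concat(go_parts, ignore_index=True))
    emit("go_enrichment.tsv", go)
    kegg = enrichment.correct_pathways(
        enrichment.enrichment_table(target_genes, refs.bundle.pathway_map, ontology="pathway"))
    emit("pathway_enrichment.tsv", kegg)
    _log("enrich", f"{int(go['significant'].sum())} GO terms, "
                   f"{int(kegg['significant'].sum())} pathways significant")

    # --- qpcr -------------------------------------------------------------
    expr = qpcr.expression_table(ct_table)
    comparisons = qpcr.group_compare(expr)
    qdf = qpcr.comparisons_to_frame(comparisons)
    emit("qpcr_results.tsv", qdf)
    if len(de):
        try:
            conc = qpcr.concordance_with_sequencing(qdf, de)
            emit("qpcr_concordance.tsv", conc)
            _log("qpcr", f"direction agreement {conc.attrs['agreement']:.2f}")
        except ValueError:
            _log("qpcr", "no shared miRNAs between qPCR panel and DE table")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": {**dataclasses.asdict(config),
                   "library_depths": list(config.library_depths)},
        "seed": config.seed,
        "version": __import__("ovamir").__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "digests": {name: io.file_digest(path) for name, path in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
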