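"""End-to-end pipeline: catalog -> map -> project -> cluster -> filter ->
genes -> expression -> enrichment -> haplotypes, with per-stage TSV reports.

Each stage logs record counts in/out (the filter-cascade audit trail) and
every output carries the configuration hash and seed in its comment header.
Reruns with the same inputs, seed and configuration are byte-identical.
"""
from __future__ import annotations

import logging
import sys
from pathlib import Path

import pandas as pd

from . import cg_miner, consensus_map, haplotype_tools, mqtl_engine, reports
from .config import RunConfig
from .qtl_catalog import finalize_catalog, read_catalog

__all__ = ["run_pipeline"]

log = logging.getLogger("metaqtl")


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(name)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute every stage and write the report workspace.

    Returns a summary dict with the headline counts of each stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    meta = {"config_hash": config.digest(), "seed": config.seed}
    summary: dict[str, object] = dict(meta)

    # stage 1: catalog
    studies, records = read_catalog(config.path("catalog"), config.path("studies"))
    finalized = finalize_catalog(records, studies)
    log.info("catalog: %d studies, %d records in, %d finalized", len(studies), len(records), len(finalized))
    summary["n_studies"] = len(studies)
    summary["n_initial_qtls"] = len(finalized)

    # stage 2: consensus map + projection
    cmap = consensus_map.read_marker_table(config.path("markers"))
    projected = [consensus_map.project_qtl(r, cmap) for r in finalized]
    per_chrom, windows = consensus_map.map_stats(cmap)
    reports.write_tsv(per_chrom, outdir / "map_stats.tsv", meta)
    reports.write_tsv(windows, outdir / "map_density.tsv", meta)
    log.info("map: %d markers, %.1f cM cumulative", len(cmap), cmap.cumulative_length_cM())

    pqtls = [mqtl_engine.ProjectedQTL.from_record(r) for r in projected]
    proj_df = pd.DataFrame(
        [
            {"qtl_id": q.qtl_id, "chrom": q.chromosome, "x_cM": round(q.x, 4),
             "sd_cM": round(q.sd, 4), "pve": round(q.pve_percent, 2),
             "trait": q.trait.value, "study_id": q.study_id}
            for q in pqtls
        ]
    )
    reports.write_tsv(proj_df, outdir / "projected_qtls.tsv", meta)

    # stage 3: per-chromosome clustering + filtering
    mqtls = []
    for chrom in sorted({q.chromosome for q in pqtls}):
        sub = [q for q in pqtls if q.chromosome == chrom]
        model = mqtl_engine.cluster_chromosome(
            sub, small_threshold=config.small_threshold, seed=config.seed
        )
        mqtls.extend(mqtl_engine.summarize(model, sub, bp_per_cm=config.bp_per_cm))
        log.info("chrom %d: %d QTLs -> %d MQTLs (%s, AIC %.2f)",
                 chrom, len(sub), model.K, model.method, model.aic)
    selected = mqtl_engine.filter_mqtls(
        mqtls, min_avg_pve=config.min_avg_pve, min_studies=config.min_studies
    )
    summary["n_mqtls"] = len(mqtls)
    summary["n_mqtls_selected"] = len(selected)
    reports.write_tsv(reports.mqtl_table(mqtls), outdir / "mqtls_all.tsv", meta)
    reports.write_tsv(reports.mqtl_table(selected), outdir / "mqtls_selected.tsv", meta)
    reports.write_tsv(
        reports.chromosome_count_report(projected, selected),
        outdir / "chromosome_counts.tsv",
        meta,
    )
    reduction = mqtl_engine.ci_reduction_report(pqtls, mqtls)
    reports.write_tsv(reduction.round(4), outdir / "ci_reduction.tsv", meta)
    log.info("clustering: %d MQTLs, %d pass filters", len(mqtls), len(selected))

    # stage 4: gene mining
    genes = cg_miner.read_gene_table(config.path("genes"))
    per_mqtl, pooled = cg_miner.genes_in_mqtls(selected, genes)
    candidates = cg_miner.keyword_filter(pooled)
    summary["n_genes_pooled"] = len(pooled)
    summary["n_candidate_genes"] = len(candidates)
    gene_rows = [
        {"mqtl_id": mid, "gene_id": g.gene_id, "start_bp": g.start_bp,
         "end_bp": g.end_bp, "annotation": g.annotation_text}
        for mid, gl in sorted(per_mqtl.items()) for g in gl
    ]
    reports.write_tsv(pd.DataFrame(gene_rows), outdir / "genes_per_mqtl.tsv", meta)
    log.info("genes: %d pooled non-redundant, %d after keyword filter", len(pooled), len(candidates))

    # stage 5: expression cascade
    expr = cg_miner.read_expression(config.path("expression"))
    cand_ids = {g.gene_id for g in candidates}
    expr = expr[expr["gene_id"].isin(cand_ids)]
    calls, no_data = cg_miner.response_calls(expr)
    stages = cg_miner.cascade_filter(calls, fc1=config.fc1, fc2=config.fc2)
    summary["n_expression_called"] = len(calls)
    summary["n_stage_A"] = len(stages["A"])
    summary["n_stage_B"] = len(stages["B"])
    summary["n_stage_C"] = len(stages["C"])
    call_df = pd.DataFrame(
        [
            {"gene_id": c.gene_id, "fc_6h": round(c.fc_6h, 4), "fc_24h": round(c.fc_24h, 4),
             "direction_6h": c.direction_6h, "direction_24h": c.direction_24h,
             "p_6h": round(c.p_6h, 6), "p_24h": round(c.p_24h, 6), "tier": c.tier,
             "stage": ("C" if c in stages["C"] else "B" if c in stages["B"]
                       else "A" if c in stages["A"] else "-")}
            for c in calls
        ]
    )
    reports.write_tsv(call_df, outdir / "response_calls.tsv", meta)
    reports.write_tsv(cg_miner.cascade_counts(stages), outdir / "cascade_counts.tsv", meta)
    log.info("expression: %d called, %d no-data; stages A/B/C = %d/%d/%d",
             len(calls), len(no_data), len(stages["A"]), len(stages["B"]), len(stages["C"]))

    # stage 6: enrichment (P-responsive set vs all pooled meta-QTL genes)
    g2g_df = pd.read_csv(config.path("gene2go"), sep="\t")
    gene2go: dict[str, list[str]] = {}
    for _, row in g2g_df.iterrows():
        gene2go.setdefault(row["gene_id"], []).append(row["go_term"])
    foreground = [c.gene_id for c in stages["B"]]
    background = [g.gene_id for g in pooled]
    enrich = cg_miner.go_enrichment(foreground, background, gene2go)
    reports.write_tsv(enrich.round(6), outdir / "enrichment.tsv", meta)
    summary["n_enriched_terms"] = int((enrich["q"] < 0.05).sum()) if not enrich.empty else 0

    # stage 7: haplotype analysis for genes with SNP matrices and donors
    donors_path = config.path("donors")
    group_rows, freq_frames = [], []
    per_gene_superior: dict[str, set[str]] = {}
    subpop = None
    if donors_path.exists():
        subpop = haplotype_tools.read_subpop_table(config.path("subpop"))
        donors = pd.read_csv(donors_path, sep="\t")
        for _, drow in donors.iterrows():
            gid, donor = drow["gene_id"], drow["donor"]
            snp_path = Path(config.workspace) / f"{config.snp_prefix}{gid}.tsv"
            if not snp_path.exists():
                continue
            matrix = haplotype_tools.read_matrix_tsv(snp_path, gid, subpop)
            retained = haplotype_tools.filter_accessions(matrix, config.bad_fraction)
            result = haplotype_tools.group_haplotypes(retained, seed=config.seed)
            superior = haplotype_tools.superior_haplotype(result, donor, retained)
            freq_frames.append(haplotype_tools.subpop_frequency(result, retained.subpop))
            for g in result.groups:
                for acc in g.members:
                    group_rows.append(
                        {"gene_id": gid, "accession": acc, "group": g.group_id,
                         "superior": "+" if g.group_id == superior else "-"}
                    )
                if g.group_id == superior:
                    per_gene_superior[gid] = set(g.members)
            log.info("haplotypes %s: k=%d, superior=%s", gid, result.k_selected, superior)
    if group_rows:
        reports.write_tsv(pd.DataFrame(group_rows), outdir / "haplotype_groups.tsv", meta)
        reports.write_tsv(
            pd.concat(freq_frames, ignore_index=True).round(4),
            outdir / "haplotype_frequencies.tsv",
            meta,
        )
    if per_gene_superior and subpop is not None:
        donor_table = haplotype_tools.select_donors(per_gene_superior, subpop)
        reports.write_tsv(donor_table, outdir / "donor_panel.tsv", meta)
        summary["n_haplotype_genes"] = len(per_gene_superior)

    summary_df = pd.DataFrame(
        [{"key": k, "value": v} for k, v in summary.items()]
    )
    reports.write_tsv(summary_df, outdir / "summary.tsv", meta)
    return summary
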