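"""End-to-end orchestration of the synthetic study analysis.

Runs every stage in order on one simulated cohort: signal simulation, MR
calling and MR-count statistics, per-replicate DMR calling with replicate
intersection, gene association and overlap summaries, genomic-context
classification and composition tests, gene-set enrichment, drug-track overlap
and directional concordance, HMR overlap, per-CpG validation, and the
promoter-based GWAS-locus enrichment with its resampling null.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annotation import (classify_cpg_context, classify_gene_context,
                         context_composition_test, enrichment_table, term_enrichment)
from .dmr_calling import DMRParams, DMRSet, associate_genes, call_dmrs
from .gwas_enrichment import EnrichmentResult, empirical_enrichment
from .intervals import merge_intervals
from .mr_calling import MRParams, call_sample_mrs, mr_count_stats
from .overlap_validation import (cpg_validation, directional_concordance,
                                 overlap_fraction)
from .stats import fisher_exact_2x2
from .synthetic_data import (SimulationConfig, build_gene_sets, generate_annotation,
                             generate_probe_layout, simulate_cpg_table,
                             simulate_signals, simulate_truth)


@dataclass
class PipelineResult:
    config: SimulationConfig
    annotation: object
    layout: object
    truth: object
    signals: object
    mrsets: list
    mr_stats: object
    dmrs: dict  # cell_type -> (exp1, exp2, intersected DMRSet with genes)
    gene_overlap: object
    context_tables: dict  # cell_type -> labeled DMR frame
    composition_tests: dict
    enrichment: dict  # pooled and stratified term-enrichment tables
    drug_overlap: dict  # cell_type -> OverlapFractionResult
    concordance: dict  # cell_type -> list[ConcordanceResult]
    hmr_overlap: dict  # cell_type -> dict of percentages and Fisher P
    validation: dict  # cell_type -> CpGValidationSummary
    gwas: dict  # cell_type ("all" included) -> EnrichmentResult


def run_pipeline(config: SimulationConfig,
                 mr_params: MRParams = MRParams(),
                 dmr_params: DMRParams = DMRParams(),
                 gwas_n_iter: int = 10_000) -> PipelineResult:
    config.validate()
    annotation = generate_annotation(config)
    layout = generate_probe_layout(annotation, config.probe_spacing)
    truth = simulate_truth(annotation, config)
    signals = simulate_signals(annotation, layout, truth, config)

    mrsets = call_sample_mrs(signals, layout, mr_params)
    mr_stats = mr_count_stats(mrsets, signals.sample_sheet)

    dmrs: dict[str, tuple] = {}
    for ct in config.cell_types:
        dmrs[ct] = call_dmrs(signals, layout, ct, dmr_params)
    annotated, gene_overlap = associate_genes(
        {ct: triple[2] for ct, triple in dmrs.items()}, annotation)
    dmrs = {ct: (dmrs[ct][0], dmrs[ct][1], annotated[ct]) for ct in dmrs}

    context_tables, composition_tests = {}, {}
    for ct, (_, _, inter) in dmrs.items():
        regions = inter.regions.copy()
        if len(regions):
            regions["cpg_context"] = classify_cpg_context(regions, annotation.cpg_islands)
            regions["gene_context"] = classify_gene_context(regions, annotation)
        context_tables[ct] = regions
        hyper = regions[regions["direction"] == "hyper"] if len(regions) else regions
        hypo = regions[regions["direction"] == "hypo"] if len(regions) else regions
        if len(hyper) and len(hypo):
            composition_tests[ct] = {
                "cpg": context_composition_test(hyper["cpg_context"], hypo["cpg_context"]),
                "gene": context_composition_test(hyper["gene_context"],
                                                 hypo["gene_context"]),
            }

    gene_sets = build_gene_sets(truth, annotation, config)
    background = list(annotation.genes["gene_id"])
    all_query, strata = set(), {}
    per_ct_genes = {}
    for ct, (_, _, inter) in dmrs.items():
        genes = set()
        for gl in inter.regions.get("genes", pd.Series(dtype=str)):
            genes.update(g for g in str(gl).split(",") if g)
        per_ct_genes[ct] = genes
        all_query |= genes
    cts = list(config.cell_types)
    for g in all_query:
        hits = [ct for ct in cts if g in per_ct_genes[ct]]
        strata[g] = "common" if len(hits) > 1 else hits[0]
    enrichment = {}
    if all_query:
        res = term_enrichment(sorted(all_query), background, gene_sets, strata=strata,
                              sort_stratum=cts[0] if cts else None)
        enrichment["pooled"] = enrichment_table(res)
        for ct in cts:
            for direction in ("hyper", "hypo"):
                sub = dmrs[ct][2].regions
                q = set()
                for _, r in sub[sub["direction"] == direction].iterrows():
                    q.update(g for g in str(r.get("genes", "")).split(",") if g)
                if q:
                    r2 = term_enrichment(sorted(q), background, gene_sets)
                    enrichment[f"{ct}_{direction}"] = enrichment_table(r2)

    drug_tracks = {cond: sub[["chrom", "start", "end", "direction"]].assign(condition=cond)
                   for cond, sub in truth.drug.groupby("condition")}
    drug_all = pd.concat(drug_tracks.values(), ignore_index=True) if drug_tracks else \
        pd.DataFrame(columns=["chrom", "start", "end", "direction", "condition"])
    drug_overlap, concordance = {}, {}
    hmr_overlap, validation = {}, {}
    for ct, (_, _, inter) in dmrs.items():
        regions = inter.regions
        if len(regions) == 0:
            continue
        drug_overlap[ct] = overlap_fraction(regions, drug_tracks, mode="per_condition")
        concordance[ct] = directional_concordance(regions, drug_all)
        # HMR overlap: called MRs (controls, merged per cell type) vs DMRs
        hmr_track = truth.hmrs[truth.hmrs["cell_type"] == ct]
        ctrl_mrs = pd.concat(
            [m.regions for m in mrsets
             if m.cell_type == ct and m.sample_id.startswith("ctrl")],
            ignore_index=True)
        mr_merged = merge_intervals(ctrl_mrs) if len(ctrl_mrs) else ctrl_mrs
        if len(mr_merged) and len(hmr_track):
            mr_pct = overlap_fraction(mr_merged, hmr_track).percent
            dmr_pct = overlap_fraction(regions, hmr_track).percent
            mr_n = len(mr_merged)
            dmr_n = len(regions)
            mr_hit = int(round(mr_pct / 100.0 * mr_n))
            dmr_hit = int(round(dmr_pct / 100.0 * dmr_n))
            fisher = fisher_exact_2x2(dmr_hit, dmr_n - dmr_hit, mr_hit, mr_n - mr_hit)
            hmr_overlap[ct] = {"mr_pct": mr_pct, "dmr_pct": dmr_pct,
                               "odds_ratio": fisher.odds_ratio, "p_value": fisher.p_value}
        cpg_table = simulate_cpg_table(annotation, truth, config, ct)
        validation[ct] = cpg_validation(regions, cpg_table)

    loci = truth.gwas_loci[["chrom", "start", "end"]]
    promoters = annotation.promoters
    gwas = {}
    seed_base = int(config.seed) % (2 ** 31 - 1)
    for label, regions in [("all", pd.concat([d[2].regions for d in dmrs.values()],
                                             ignore_index=True))] + \
                          [(ct, dmrs[ct][2].regions) for ct in dmrs]:
        if len(regions) == 0:
            continue
        label_salt = zlib.crc32(label.encode()) % 1000
        gwas[label] = empirical_enrichment(regions, loci, promoters,
                                           n_iter=gwas_n_iter,
                                           seed=(seed_base + label_salt) % (2 ** 31))
    return PipelineResult(
        config=config, annotation=annotation, layout=layout, truth=truth,
        signals=signals, mrsets=mrsets, mr_stats=mr_stats, dmrs=dmrs,
        gene_overlap=gene_overlap, context_tables=context_tables,
        composition_tests=composition_tests, enrichment=enrichment,
        drug_overlap=drug_overlap, concordance=concordance,
        hmr_overlap=hmr_overlap, validation=validation, gwas=gwas)


def summarize(result: PipelineResult) -> dict:
    """Flat dictionary of the pipeline's headline numbers."""
    out: dict[str, object] = {}
    counts = result.mr_stats.counts
    for (ct, grp), sub in counts.groupby(["cell_type", "group"]):
        out[f"mr_count_median_{ct}_{grp}"] = float(sub["mr_count"].median())
    for _, row in result.mr_stats.comparisons.iterrows():
        out[f"mr_p_{row['label']}"] = float(row["p_value"])
    for ct, (e1, e2, inter) in result.dmrs.items():
        out[f"dmr_count_{ct}"] = len(inter)
        if len(inter):
            out[f"dmr_fraction_hypo_{ct}"] = float(
                (inter.regions["direction"] == "hypo").mean())
    for _, row in result.gene_overlap.pairwise.iterrows():
        if row["set_a"].split("_")[-1] == row["set_b"].split("_")[-1]:
            out[f"gene_overlap_pct_{row['set_a']}__{row['set_b']}"] = \
                float(row["pct_of_smaller"])
    for ct, ov in result.drug_overlap.items():
        out[f"drug_overlap_pct_{ct}"] = float(ov.percent)
    for ct, results in result.concordance.items():
        for r in results:
            out[f"concordance_p_{ct}_{r.bd_direction}_bd_x_{r.track_direction}_track"] = \
                float(r.p_value)
            out[f"concordance_or_{ct}_{r.bd_direction}_bd_x_{r.track_direction}_track"] = \
                float(r.odds_ratio)
    for ct, h in result.hmr_overlap.items():
        out[f"hmr_overlap_pct_mr_{ct}"] = float(h["mr_pct"])
        out[f"hmr_overlap_pct_dmr_{ct}"] = float(h["dmr_pct"])
        out[f"hmr_overlap_p_{ct}"] = float(h["p_value"])
    for ct, v in result.validation.items():
        for direction, rate in v.rate_by_direction.items():
            out[f"validation_rate_pct_{ct}_{direction}"] = float(rate)
        out[f"validation_mean_meth_diff_pct_{ct}"] = float(v.mean_meth_diff)
    for label, g in result.gwas.items():
        out[f"gwas_overlap_promoters_{label}"] = int(g.observed)
        out[f"gwas_fisher_p_{label}"] = float(g.fisher_p)
        out[f"gwas_empirical_p_{label}"] = float(g.empirical_p)
        out[f"gwas_direction_{label}"] = g.direction
    return out


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    """Deterministic text outputs for the whole run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(outdir / "mr_counts.tsv", result.mr_stats.counts)
    io.write_tsv(outdir / "mr_comparisons.tsv", result.mr_stats.comparisons)
    io.write_tsv(outdir / "mr_covariate_tests.tsv", result.mr_stats.covariate_tests)
    for ct, (e1, e2, inter) in result.dmrs.items():
        io.write_tsv(outdir / f"dmrs_{ct}_exp1.tsv", e1.regions)
        io.write_tsv(outdir / f"dmrs_{ct}_exp2.tsv", e2.regions)
        io.write_tsv(outdir / f"dmrs_{ct}_intersect.tsv", inter.regions)
    io.write_tsv(outdir / "gene_overlap_pairwise.tsv", result.gene_overlap.pairwise)
    io.write_tsv(outdir / "gene_overlap_venn.tsv", result.gene_overlap.venn)
    for ct, table in result.context_tables.items():
        io.write_tsv(outdir / f"dmr_context_{ct}.tsv", table)
    for name, table in result.enrichment.items():
        io.write_tsv(outdir / f"term_enrichment_{name}.tsv", table)
    for ct, v in result.validation.items():
        io.write_tsv(outdir / f"cpg_validation_{ct}.tsv", v.per_dmr)
    io.write_json(outdir / "gwas_enrichment.json",
                  {label: g.to_dict() for label, g in result.gwas.items()})
    io.write_json(outdir / "summary.json", summarize(result))
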