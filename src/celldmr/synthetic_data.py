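"""Synthetic promoter-methylation study generator.

Emulates an MBD-enrichment promoter tiling-array experiment on NeuN-sorted
neuronal and nonneuronal nuclei from a case/control cohort: a toy genome with
non-overlapping promoter tiles (TSS-7.5 kb .. TSS+2.5 kb) tiled by 25-mer
probes at 35 bp spacing, per-sample log-ratio-like enrichment signal against a
whole-genome-amplified (unmethylated) reference, duplicate technical
experiments per sample, covariates, and auxiliary interval tracks
(drug-induced DMRs with controllable opposite-direction concordance,
hydroxymethylated regions, GWAS loci with a configurable planted enrichment).

Every stochastic step draws from ``numpy.random.default_rng`` seeded from
``SimulationConfig.seed`` with a per-operation salt, so each operation is
deterministic given the config alone, independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import sort_intervals

PROBE_LENGTH = 25

# per-operation rng salts (kept stable; changing one changes that op's stream only)
_SALT = {
    "annotation": 11,
    "truth": 23,
    "signals": 37,
    "cpg": 53,
    "genesets": 71,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SizingError(ConfigError):
    """Requested layout does not fit in the genome."""


class InfeasibleError(ConfigError):
    """Requested overlap/fraction structure is mutually infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic experiment.

    Defaults mirror the emulated study design: a 34-patient / 35-control
    cohort, two cell types, duplicate experiments, 35 bp probe spacing on
    10 kb promoter tiles, and a mostly-hypomethylated planted DMR mix.
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 6_000_000), ("chr2", 6_000_000))
    n_genes: int = 1000
    cell_types: tuple[str, ...] = ("neuron", "nonneuron")
    n_cases: int = 34
    n_controls: int = 35
    n_replicates: int = 2
    probe_spacing: int = 35
    tile_upstream: int = 7500
    tile_downstream: int = 2500
    min_tile_gap: int = 1500
    cpg_island_fraction: float = 0.6
    # baseline methylation probability per cell type (fewer methylated
    # promoters in neurons than nonneurons, as in sorted-nuclei methylomes)
    baseline_meth_prob: tuple[tuple[str, float], ...] = (("neuron", 0.30), ("nonneuron", 0.38))
    core_active_prob: float = 0.9  # per-subject activity of each methylated core
    methylated_level: float = 1.0  # enrichment log-ratio of a methylated region
    noise_sd: float = 0.25  # per-probe, per-replicate Gaussian noise SD
    sample_effect_sd: float = 0.05  # per-sample global offset SD (shared by replicates)
    dmr_fraction: float = 0.08  # fraction of promoters with a planted DMR, per cell type
    dmr_shared_fraction: float = 0.35  # DMR promoters shared between cell types
    fraction_hypo: float = 0.7  # planted DMRs hypomethylated in patients
    effect_sizes: tuple[float, ...] = (3.0, 4.0, 6.0)  # signal shift in noise-SD units
    hmr_fraction: float = 0.10
    hmr_dmr_odds: float = 1.5  # odds boost of HMR membership for DMR promoters
    drug_conditions: tuple[str, ...] = ("Li_min", "Li_max", "Val_min", "Val_max",
                                        "Car_min", "Car_max")
    drug_concordance_fraction: float = 0.35  # planted DMRs overlapped by >=1 condition
    drug_flip_probability: float = 0.9  # overlap has the opposite direction
    drug_background_rate: float = 0.05  # per-condition rate on non-DMR promoters
    gwas_n_loci: int = 60
    gwas_enrichment_odds: float = 2.0  # odds of a DMR promoter lying in a locus
    gwas_locus_padding: int = 500
    confound_covariate: str | None = None  # e.g. "age": couples covariate to MR burden
    confound_strength: float = 0.0  # change in core-active prob per covariate SD
    cpg_spacing: int = 150  # RRBS-style CpG table: mean bp between covered CpGs
    cpg_read_depth: int = 60  # pooled reads per CpG per group
    cpg_meth_diff: float = 0.15  # true case-control methylation difference at DMR CpGs
    seed: int = 0

    @property
    def tile_width(self) -> int:
        return self.tile_upstream + self.tile_downstream

    def baseline_prob(self, cell_type: str) -> float:
        return dict(self.baseline_meth_prob)[cell_type]

    def validate(self) -> "SimulationConfig":
        for name in ("cpg_island_fraction", "core_active_prob", "dmr_fraction",
                     "dmr_shared_fraction", "fraction_hypo", "hmr_fraction",
                     "drug_concordance_fraction", "drug_flip_probability",
                     "drug_background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_cases", "n_controls", "n_replicates",
                     "probe_spacing", "gwas_n_loci"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v}")
        if self.probe_spacing < PROBE_LENGTH:
            raise ConfigError(
                f"probe_spacing ({self.probe_spacing}) must be >= probe length ({PROBE_LENGTH})")
        if self.noise_sd < 0 or self.sample_effect_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        if any(e < 0 for e in self.effect_sizes) or not self.effect_sizes:
            raise ConfigError("effect_sizes must be non-empty and non-negative")
        if self.gwas_enrichment_odds <= 0:
            raise ConfigError("gwas_enrichment_odds must be positive")
        for ct in self.cell_types:
            if ct not in dict(self.baseline_meth_prob):
                raise ConfigError(f"no baseline_meth_prob for cell type {ct!r}")
        return self

    def rng(self, op: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _SALT[op], extra]))


@dataclass
class GenomeAnnotation:
    """Toy genome: chromosomes, genes with simple exon/UTR models, CpG islands,
    and one promoter tile per gene (strand-mirrored around the TSS)."""

    chromosomes: tuple[tuple[str, int], ...]
    genes: pd.DataFrame  # gene_id, chrom, strand, tss, start, end
    gene_features: pd.DataFrame  # gene_id, feature, chrom, start, end
    cpg_islands: pd.DataFrame  # chrom, start, end
    promoters: pd.DataFrame  # gene_id, chrom, start, end

    def validate(self) -> "GenomeAnnotation":
        lengths = dict(self.chromosomes)
        for name, df in (("genes", self.genes), ("cpg_islands", self.cpg_islands),
                         ("promoters", self.promoters), ("gene_features", self.gene_features)):
            if df.empty:
                continue
            for _, row in df.iterrows():
                if row["chrom"] not in lengths:
                    raise ConfigError(f"{name}: unknown chromosome {row['chrom']}")
                if not (0 <= row["start"] < row["end"] <= lengths[row["chrom"]]):
                    raise ConfigError(f"{name}: interval outside chromosome bounds")
        if set(self.promoters["gene_id"]) != set(self.genes["gene_id"]):
            raise ConfigError("each gene must have exactly one promoter tile")
        spans = self.genes.set_index("gene_id")
        for _, row in self.gene_features.iterrows():
            g = spans.loc[row["gene_id"]]
            if row["feature"] != "promoter" and not (g["start"] <= row["start"]
                                                     and row["end"] <= g["end"]):
                raise ConfigError(
                    f"gene_features: {row['feature']} of {row['gene_id']} outside gene span")
        return self


@dataclass
class ProbeLayout:
    """Probes tiling the promoter set; ordered by (gene, offset)."""

    probes: pd.DataFrame  # probe_id, chrom, start, end, gene_id
    spacing: int

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class TruthTable:
    """Planted ground truth for every downstream stage."""

    baseline: pd.DataFrame  # gene_id, cell_type, methylated, chrom, core_start, core_end
    dmrs: pd.DataFrame  # gene_id, cell_type, chrom, start, end, direction, effect_size
    hmrs: pd.DataFrame  # gene_id, cell_type, chrom, start, end
    drug: pd.DataFrame  # condition, gene_id, chrom, start, end, direction, source
    gwas_loci: pd.DataFrame  # locus_id, chrom, start, end, gene_id
    gwas_membership: pd.DataFrame  # gene_id, in_locus (bool)

    def dmr_track(self, cell_type: str) -> pd.DataFrame:
        sub = self.dmrs[self.dmrs["cell_type"] == cell_type]
        return sort_intervals(sub[["chrom", "start", "end", "direction", "gene_id",
                                   "effect_size"]])


@dataclass
class SignalBundle:
    """Probe x column signal matrix plus its sample sheet.

    Columns are named ``<subject>_<cell_type>.e<replicate>`` for samples and
    ``ref.e<replicate>`` for the whole-genome-amplified reference.
    """

    signals: pd.DataFrame  # index: probe_id, columns per sample-replicate
    sample_sheet: pd.DataFrame  # column, sample_id, subject, group, cell_type, replicate, covariates

    def reference_columns(self) -> list[str]:
        return list(self.sample_sheet.loc[self.sample_sheet["group"] == "reference", "column"])

    def sample_columns(self, cell_type: str | None = None,
                       replicate: int | None = None) -> pd.DataFrame:
        sheet = self.sample_sheet[self.sample_sheet["group"] != "reference"]
        if cell_type is not None:
            sheet = sheet[sheet["cell_type"] == cell_type]
        if replicate is not None:
            sheet = sheet[sheet["replicate"] == replicate]
        return sheet


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping promoter tiles, gene models and CpG islands.

    Genes are apportioned to chromosomes by length (largest remainder); tiles
    are separated by at least ``min_tile_gap`` bp with the leftover slack
    distributed randomly, so the layout is deterministic given the seed.
    """
    config.validate()
    rng = config.rng("annotation")
    w, g = config.tile_width, config.min_tile_gap
    lengths = np.array([L for _, L in config.chromosomes], dtype=float)
    quota = config.n_genes * lengths / lengths.sum()
    n_per = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - n_per))[: config.n_genes - n_per.sum()]:
        n_per[i] += 1
    rows, feat_rows, isl_rows = [], [], []
    gene_no = 0
    for (chrom, length), n_c in zip(config.chromosomes, n_per):
        need = n_c * w + (n_c + 1) * g
        if need > length:
            raise SizingError(
                f"{n_c} promoter tiles of {w} bp with {g} bp gaps need {need} bp "
                f"but {chrom} is only {length} bp")
        if n_c == 0:
            continue
        slack = length - need
        extra = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1))) if slack else \
            np.zeros(n_c + 1, dtype=int)
        gaps = g + extra
        starts = np.cumsum(gaps[:-1]) + np.arange(n_c) * w
        strands = rng.choice(["+", "-"], size=n_c)
        for s, strand in zip(starts, strands):
            gid = f"G{gene_no:05d}"
            gene_no += 1
            tile_start, tile_end = int(s), int(s) + w
            tss = tile_start + (config.tile_upstream if strand == "+" else config.tile_downstream)
            gene_len = int(rng.integers(5000, 30001))
            if strand == "+":
                g_start, g_end = tss, min(tss + gene_len, length)
            else:
                g_start, g_end = max(tss + 1 - gene_len, 0), tss + 1
            rows.append((gid, chrom, strand, tss, g_start, g_end))
            feat_rows.extend(_gene_features(gid, chrom, strand, g_start, g_end, rng))
            if rng.random() < config.cpg_island_fraction:
                hw1, hw2 = rng.integers(250, 751, size=2)
                isl_rows.append((chrom, max(tss - int(hw1), tile_start),
                                 min(tss + int(hw2), tile_end)))
        # promoter tiles derived from gene rows below
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"])
    promoters = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "chrom": genes["chrom"],
        "start": np.where(genes["strand"] == "+", genes["tss"] - config.tile_upstream,
                          genes["tss"] - config.tile_downstream),
        "end": np.where(genes["strand"] == "+", genes["tss"] + config.tile_downstream,
                        genes["tss"] + config.tile_upstream),
    })
    ann = GenomeAnnotation(
        chromosomes=tuple(config.chromosomes),
        genes=genes,
        gene_features=pd.DataFrame(feat_rows,
                                   columns=["gene_id", "feature", "chrom", "start", "end"]),
        cpg_islands=sort_intervals(pd.DataFrame(isl_rows, columns=["chrom", "start", "end"])),
        promoters=sort_intervals(promoters),
    )
    return ann.validate()


def _gene_features(gid: str, chrom: str, strand: str, start: int, end: int,
                   rng: np.random.Generator) -> list[tuple]:
    """Minimal 3-exon gene model with terminal UTRs, strand-aware."""
    span = end - start
    utr5 = min(200, span // 10)
    utr3 = min(150, span // 10)
    exon_w = min(300, span // 5)
    # exon starts at relative positions 0, 40% and (span - exon_w)
    rel_exons = [(0, exon_w), (int(span * 0.4), int(span * 0.4) + exon_w),
                 (span - exon_w, span)]
    feats = []
    if strand == "+":
        feats.append((gid, "five_prime_utr", chrom, start, start + utr5))
        feats.append((gid, "three_prime_utr", chrom, end - utr3, end))
        abs_exons = [(start + a, start + b) for a, b in rel_exons]
    else:
        feats.append((gid, "five_prime_utr", chrom, end - utr5, end))
        feats.append((gid, "three_prime_utr", chrom, start, start + utr3))
        abs_exons = [(end - b, end - a) for a, b in rel_exons]
        abs_exons.sort()
    prev_end = None
    for a, b in abs_exons:
        feats.append((gid, "exon", chrom, a, b))
        if prev_end is not None and prev_end < a:
            feats.append((gid, "intron", chrom, prev_end, a))
        prev_end = b
    return feats


def generate_probe_layout(annotation: GenomeAnnotation,
                          spacing: int = 35,
                          probe_length: int = PROBE_LENGTH) -> ProbeLayout:
    """Tile each promoter with probes at fixed spacing.

    Convention: ``floor(tile_width / spacing)`` probes per tile; probe *i*
    starts at ``tile_start + i * spacing`` and spans ``probe_length`` bp, so
    the last probe always ends inside the tile.
    """
    if spacing < probe_length:
        raise ConfigError(f"spacing ({spacing}) must be >= probe length ({probe_length})")
    frames = []
    for _, row in annotation.promoters.iterrows():
        width = row["end"] - row["start"]
        n = width // spacing
        starts = row["start"] + np.arange(n) * spacing
        frames.append(pd.DataFrame({
            "probe_id": [f"{row['gene_id']}:{i:04d}" for i in range(n)],
            "chrom": row["chrom"],
            "start": starts,
            "end": starts + probe_length,
            "gene_id": row["gene_id"],
        }))
    probes = pd.concat(frames, ignore_index=True)
    return ProbeLayout(probes=probes, spacing=spacing)


# ---------------------------------------------------------------------------
# truth


def _segment_around_tss(rng: np.random.Generator, tss: int, tile_start: int,
                        tile_end: int, lo: int = 400, hi: int = 1000) -> tuple[int, int]:
    w1, w2 = rng.integers(lo, hi + 1, size=2)
    return max(tss - int(w1), tile_start), min(tss + int(w2), tile_end)


def simulate_truth(annotation: GenomeAnnotation, config: SimulationConfig) -> TruthTable:
    """Plant baseline methylation, DMRs, HMRs, drug-responsive regions and GWAS loci.

    Hypomethylated DMRs are planted on baseline-methylated promoters (their
    region is the methylated core, which patients lose); hypermethylated DMRs
    on baseline-unmethylated promoters (patients gain signal there).  GWAS
    locus anchors are drawn by weighted sampling without replacement with
    weight ``gwas_enrichment_odds`` on DMR promoters, which makes the planted
    DMR-by-locus odds ratio approximately the configured value and exactly
    uniform placement at odds 1.
    """
    config.validate()
    rng = config.rng("truth")
    genes = annotation.genes.set_index("gene_id")
    tiles = annotation.promoters.set_index("gene_id")
    gene_ids = list(annotation.genes["gene_id"])
    n_genes = len(gene_ids)

    base_rows, dmr_rows, hmr_rows = [], [], []
    meth_by_ct: dict[str, dict[str, bool]] = {}
    cores_by_ct: dict[str, dict[str, tuple[int, int]]] = {}
    for ct in config.cell_types:
        p = config.baseline_prob(ct)
        meth = rng.random(n_genes) < p
        cores: dict[str, tuple[int, int]] = {}
        for gid, m in zip(gene_ids, meth):
            tile = tiles.loc[gid]
            if m:
                cs, ce = _segment_around_tss(rng, genes.loc[gid, "tss"],
                                             tile["start"], tile["end"], 400, 1000)
                cores[gid] = (cs, ce)
                base_rows.append((gid, ct, True, tile["chrom"], cs, ce))
            else:
                base_rows.append((gid, ct, False, tile["chrom"], -1, -1))
        meth_by_ct[ct] = dict(zip(gene_ids, (bool(m) for m in meth)))
        cores_by_ct[ct] = cores

    # plant DMRs; a configurable fraction of a later cell type's DMR promoters
    # is shared (same gene and direction) with the first cell type
    n_dmr = int(round(config.dmr_fraction * n_genes))
    planted_by_ct: dict[str, dict[str, str]] = {}
    first_ct = config.cell_types[0] if config.cell_types else None
    for ct in config.cell_types:
        meth = meth_by_ct[ct]
        cores = cores_by_ct[ct]
        chosen: dict[str, str] = {}  # gene -> direction
        if ct != first_ct and config.dmr_shared_fraction > 0:
            n_shared = int(round(config.dmr_shared_fraction * n_dmr))
            feasible = [(g, d) for g, d in planted_by_ct[first_ct].items()
                        if (d == "hypo" and meth[g]) or (d == "hyper" and not meth[g])]
            if feasible:
                take = min(n_shared, len(feasible))
                idx = rng.choice(len(feasible), size=take, replace=False)
                chosen.update(feasible[i] for i in idx)
        hypo_flags = rng.random(n_dmr - len(chosen)) < config.fraction_hypo
        n_hypo = int(hypo_flags.sum())
        n_hyper = (n_dmr - len(chosen)) - n_hypo
        free_meth = [g for g in gene_ids if meth[g] and g not in chosen]
        free_unmeth = [g for g in gene_ids if not meth[g] and g not in chosen]
        if n_hypo > len(free_meth):
            raise InfeasibleError(
                f"cannot plant {n_hypo} hypo DMRs on {len(free_meth)} methylated "
                f"promoters for cell type {ct}")
        if n_hyper > len(free_unmeth):
            raise InfeasibleError(
                f"cannot plant {n_hyper} hyper DMRs on {len(free_unmeth)} unmethylated "
                f"promoters for cell type {ct}")
        for g in rng.choice(free_meth, size=n_hypo, replace=False):
            chosen[g] = "hypo"
        for g in rng.choice(free_unmeth, size=n_hyper, replace=False):
            chosen[g] = "hyper"
        planted_by_ct[ct] = chosen
        effects = rng.choice(config.effect_sizes, size=len(chosen))
        for (gid, direction), eff in zip(sorted(chosen.items()), effects):
            tile = tiles.loc[gid]
            if direction == "hypo":
                s, e = cores[gid]
            else:
                s, e = _segment_around_tss(rng, genes.loc[gid, "tss"],
                                           tile["start"], tile["end"], 400, 1000)
            dmr_rows.append((gid, ct, tile["chrom"], s, e, direction, float(eff)))
        # HMR flags, boosted on DMR promoters
        p0 = config.hmr_fraction
        p_dmr = config.hmr_dmr_odds * p0 / (1 - p0 + config.hmr_dmr_odds * p0)
        for gid in gene_ids:
            if rng.random() < (p_dmr if gid in chosen else p0):
                tile = tiles.loc[gid]
                s, e = _segment_around_tss(rng, genes.loc[gid, "tss"],
                                           tile["start"], tile["end"], 300, 800)
                hmr_rows.append((gid, ct, tile["chrom"], s, e))

    dmrs = pd.DataFrame(dmr_rows, columns=["gene_id", "cell_type", "chrom", "start",
                                           "end", "direction", "effect_size"])
    drug = _simulate_drug_truth(dmrs, annotation, config, rng)
    gwas_loci, membership = _simulate_gwas_truth(dmrs, annotation, config, rng)
    return TruthTable(
        baseline=pd.DataFrame(base_rows, columns=["gene_id", "cell_type", "methylated",
                                                  "chrom", "core_start", "core_end"]),
        dmrs=dmrs,
        hmrs=pd.DataFrame(hmr_rows, columns=["gene_id", "cell_type", "chrom", "start", "end"]),
        drug=drug,
        gwas_loci=gwas_loci,
        gwas_membership=membership,
    )


def _simulate_drug_truth(dmrs: pd.DataFrame, annotation: GenomeAnnotation,
                         config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Drug-induced DMR tracks, one per condition.

    Each planted disease DMR is overlapped by a drug region (1-2 random
    conditions, same interval) with probability ``drug_concordance_fraction``;
    the drug region takes the opposite direction with probability
    ``drug_flip_probability``.  Background drug regions are placed only on
    promoters with no planted DMR.
    """
    conditions = list(config.drug_conditions)
    tiles = annotation.promoters.set_index("gene_id")
    genes = annotation.genes.set_index("gene_id")
    rows = []
    seen = set()
    for _, d in dmrs.iterrows():
        key = (d["chrom"], d["start"], d["end"])
        if key in seen:  # same region planted in both cell types: one drug decision
            continue
        seen.add(key)
        if rng.random() < config.drug_concordance_fraction:
            flip = rng.random() < config.drug_flip_probability
            direction = ({"hypo": "hyper", "hyper": "hypo"}[d["direction"]]
                         if flip else d["direction"])
            for cond in rng.choice(conditions, size=int(rng.integers(1, 3)), replace=False):
                rows.append((cond, d["gene_id"], d["chrom"], d["start"], d["end"],
                             direction, "planted"))
    dmr_genes = set(dmrs["gene_id"])
    for gid in annotation.genes["gene_id"]:
        if gid in dmr_genes:
            continue
        for cond in conditions:
            if rng.random() < config.drug_background_rate:
                tile = tiles.loc[gid]
                s, e = _segment_around_tss(rng, genes.loc[gid, "tss"],
                                           tile["start"], tile["end"], 300, 800)
                rows.append((cond, gid, tile["chrom"], s, e,
                             str(rng.choice(["hyper", "hypo"])), "background"))
    return pd.DataFrame(rows, columns=["condition", "gene_id", "chrom", "start", "end",
                                       "direction", "source"])


def _simulate_gwas_truth(dmrs: pd.DataFrame, annotation: GenomeAnnotation,
                         config: SimulationConfig,
                         rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    gene_ids = list(annotation.genes["gene_id"])
    if config.gwas_n_loci > len(gene_ids):
        raise InfeasibleError(
            f"gwas_n_loci ({config.gwas_n_loci}) exceeds gene count ({len(gene_ids)})")
    dmr_genes = set(dmrs["gene_id"])
    weights = np.array([config.gwas_enrichment_odds if g in dmr_genes else 1.0
                        for g in gene_ids])
    # Efraimidis-Spirakis weighted sampling without replacement
    keys = rng.random(len(gene_ids)) ** (1.0 / weights)
    anchors = [gene_ids[i] for i in np.argsort(-keys)[: config.gwas_n_loci]]
    tiles = annotation.promoters.set_index("gene_id")
    lengths = dict(annotation.chromosomes)
    rows = []
    for i, gid in enumerate(sorted(anchors)):
        tile = tiles.loc[gid]
        pad = config.gwas_locus_padding
        rows.append((f"L{i:03d}", tile["chrom"], max(tile["start"] - pad, 0),
                     min(tile["end"] + pad, lengths[tile["chrom"]]), gid))
    loci = sort_intervals(pd.DataFrame(rows, columns=["locus_id", "chrom", "start",
                                                      "end", "gene_id"]))
    anchor_set = set(anchors)
    membership = pd.DataFrame({"gene_id": gene_ids,
                               "in_locus": [g in anchor_set for g in gene_ids]})
    return loci, membership


# ---------------------------------------------------------------------------
# signals


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float,
                      size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    while True:
        bad = out < low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


_COV_SCALE = {"age": (45.0, 10.0), "pmi": (30.0, 10.0), "ph": (6.5, 0.25),
              "onset": (25.0, 8.0), "duration": (20.0, 10.0),
              "antipsychotics": (10000.0, 10000.0)}


def _draw_covariates(rng: np.random.Generator, subjects: Sequence[str],
                     groups: Sequence[str]) -> pd.DataFrame:
    n = len(subjects)
    age = np.round(_truncated_normal(rng, 45, 10, 18, n), 1)
    pmi = np.round(_truncated_normal(rng, 30, 10, 1, n), 1)
    ph = np.round(rng.normal(6.5, 0.25, n), 2)
    onset = np.round(_truncated_normal(rng, 25, 8, 12, n), 1)
    onset = np.minimum(onset, age - 1.0)
    duration = np.round(age - onset, 1)
    antipsy = np.round(np.exp(rng.normal(9.0, 1.0, n)), 0)
    is_case = np.array([g == "case" for g in groups])
    df = pd.DataFrame({"subject": subjects, "group": groups, "age": age,
                       "pmi": pmi, "ph": ph,
                       "onset": np.where(is_case, onset, np.nan),
                       "duration": np.where(is_case, duration, np.nan),
                       "antipsychotics": np.where(is_case, antipsy, np.nan)})
    return df


def _probe_slice(layout: ProbeLayout, gene_id: str, start: int, end: int,
                 gene_index: Mapping[str, tuple[int, int]]) -> slice:
    """Positional slice of layout probes of one gene overlapping [start, end)."""
    lo, hi = gene_index[gene_id]
    starts = layout.probes["start"].to_numpy()[lo:hi]
    ends = layout.probes["end"].to_numpy()[lo:hi]
    i0 = int(np.searchsorted(ends, start, side="right"))
    i1 = int(np.searchsorted(starts, end, side="left"))
    return slice(lo + i0, lo + i1)


def _gene_probe_index(layout: ProbeLayout) -> dict[str, tuple[int, int]]:
    idx = {}
    gids = layout.probes["gene_id"].to_numpy()
    change = np.flatnonzero(np.r_[True, gids[1:] != gids[:-1], True])
    for a, b in zip(change[:-1], change[1:]):
        idx[gids[a]] = (int(a), int(b))
    return idx


def simulate_signals(annotation: GenomeAnnotation, layout: ProbeLayout,
                     truth: TruthTable, config: SimulationConfig) -> SignalBundle:
    """Per-probe enrichment signal for every sample-replicate column.

    signal = baseline(methylated core, if active in that subject)
           + case-group shift at planted DMR probes (+/- effect x noise SD)
           + per-sample offset (shared by the two replicates)
           + per-probe, per-replicate Gaussian noise.

    Cores carrying a planted DMR are always active (the planted contrast is
    the ground truth to recover); random core inactivity models
    subject-to-subject methylation-burden variability at the remaining
    promoters.  Hypomethylation shifts are clipped at the methylated level,
    so a strong effect removes the core signal entirely without undershooting
    the unmethylated baseline.
    """
    config.validate()
    rng = config.rng("signals")
    n_probes = len(layout)
    gene_index = _gene_probe_index(layout)

    subjects = [f"case{i + 1:02d}" for i in range(config.n_cases)] + \
               [f"ctrl{i + 1:02d}" for i in range(config.n_controls)]
    groups = ["case"] * config.n_cases + ["control"] * config.n_controls
    covariates = _draw_covariates(rng, subjects, groups)

    conf_z = np.zeros(len(subjects))
    if config.confound_covariate is not None and config.confound_strength != 0.0:
        mean, sd = _COV_SCALE[config.confound_covariate]
        vals = covariates[config.confound_covariate].to_numpy(dtype=float)
        vals = np.where(np.isnan(vals), mean, vals)
        conf_z = (vals - mean) / sd

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for ct in config.cell_types:
        base = truth.baseline[(truth.baseline["cell_type"] == ct)
                              & truth.baseline["methylated"]]
        core_slices = [_probe_slice(layout, r["gene_id"], r["core_start"], r["core_end"],
                                    gene_index) for _, r in base.iterrows()]
        dmr_sub = truth.dmrs[truth.dmrs["cell_type"] == ct]
        dmr_slices = [(_probe_slice(layout, r["gene_id"], r["start"], r["end"], gene_index),
                       r["direction"], r["effect_size"], r["gene_id"])
                      for _, r in dmr_sub.iterrows()]
        core_gene = {r["gene_id"]: i for i, (_, r) in enumerate(base.iterrows())}
        dmr_genes = set(dmr_sub["gene_id"])
        forced = np.array([r["gene_id"] in dmr_genes for _, r in base.iterrows()])
        for s_i, (subject, group) in enumerate(zip(subjects, groups)):
            sample_id = f"{subject}_{ct}"
            p_active = float(np.clip(config.core_active_prob
                                     + config.confound_strength * conf_z[s_i], 0.02, 1.0))
            active = rng.random(len(core_slices)) < p_active
            active |= forced
            mean_vec = np.zeros(n_probes)
            for sl, act in zip(core_slices, active):
                if act:
                    mean_vec[sl] += config.methylated_level
            if group == "case":
                for sl, direction, eff, gid in dmr_slices:
                    shift = eff * config.noise_sd
                    if direction == "hypo":
                        # patients lose (up to all of) the methylated core signal
                        mean_vec[sl] -= min(shift, config.methylated_level)
                    else:
                        mean_vec[sl] += shift
            sample_offset = rng.normal(0.0, config.sample_effect_sd) \
                if config.sample_effect_sd > 0 else 0.0
            for rep in range(1, config.n_replicates + 1):
                col = f"{sample_id}.e{rep}"
                noise = rng.normal(0.0, config.noise_sd, n_probes) \
                    if config.noise_sd > 0 else 0.0
                columns[col] = mean_vec + sample_offset + noise
                cov = covariates.iloc[s_i]
                sheet_rows.append({
                    "column": col, "sample_id": sample_id, "subject": subject,
                    "group": group, "cell_type": ct, "replicate": rep,
                    "age": cov["age"], "pmi": cov["pmi"], "ph": cov["ph"],
                    "onset": cov["onset"], "duration": cov["duration"],
                    "antipsychotics": cov["antipsychotics"],
                })
    for rep in range(1, config.n_replicates + 1):
        col = f"ref.e{rep}"
        noise = rng.normal(0.0, config.noise_sd, n_probes) if config.noise_sd > 0 else \
            np.zeros(n_probes)
        columns[col] = noise
        sheet_rows.append({"column": col, "sample_id": "ref", "subject": "ref",
                           "group": "reference", "cell_type": "reference",
                           "replicate": rep, "age": np.nan, "pmi": np.nan, "ph": np.nan,
                           "onset": np.nan, "duration": np.nan, "antipsychotics": np.nan})
    signals = pd.DataFrame(columns, index=pd.Index(layout.probes["probe_id"], name="probe_id"))
    return SignalBundle(signals=signals, sample_sheet=pd.DataFrame(sheet_rows))


# ---------------------------------------------------------------------------
# RRBS-style per-CpG table


def simulate_cpg_table(annotation: GenomeAnnotation, truth: TruthTable,
                       config: SimulationConfig, cell_type: str) -> pd.DataFrame:
    """Pooled per-CpG methylated/unmethylated counts for cases and controls.

    CpGs are placed at roughly ``cpg_spacing`` bp inside baseline cores and
    planted DMR regions.  True methylation fractions: 0.8 inside methylated
    regions, 0.1 outside; planted DMRs shift the case fraction by
    ``cpg_meth_diff`` in the planted direction.  Counts are binomial draws at
    ``cpg_read_depth`` pooled reads per group.
    """
    rng = config.rng("cpg", extra=list(config.cell_types).index(cell_type))
    base = truth.baseline[(truth.baseline["cell_type"] == cell_type)
                          & truth.baseline["methylated"]]
    dmrs = truth.dmrs[truth.dmrs["cell_type"] == cell_type]
    dmr_by_gene = {r["gene_id"]: r for _, r in dmrs.iterrows()}
    rows = []
    regions = [(r["gene_id"], r["chrom"], r["core_start"], r["core_end"], True)
               for _, r in base.iterrows()]
    regions += [(r["gene_id"], r["chrom"], r["start"], r["end"], False)
                for _, r in dmrs.iterrows() if r["direction"] == "hyper"]
    for gid, chrom, start, end, methylated in regions:
        n_cpg = max(1, (end - start) // config.cpg_spacing)
        positions = np.sort(rng.integers(start, end, size=n_cpg))
        frac_ctrl = 0.8 if methylated else 0.1
        frac_case = frac_ctrl
        d = dmr_by_gene.get(gid)
        if d is not None:
            delta = config.cpg_meth_diff if d["direction"] == "hyper" else -config.cpg_meth_diff
            in_dmr = (positions >= d["start"]) & (positions < d["end"])
        else:
            delta, in_dmr = 0.0, np.zeros(n_cpg, dtype=bool)
        for pos, hit in zip(positions, in_dmr):
            fc = float(np.clip(frac_case + (delta if hit else 0.0), 0.01, 0.99))
            n_case = int(rng.poisson(config.cpg_read_depth))
            n_ctrl = int(rng.poisson(config.cpg_read_depth))
            m_case = int(rng.binomial(n_case, fc)) if n_case else 0
            m_ctrl = int(rng.binomial(n_ctrl, frac_ctrl)) if n_ctrl else 0
            rows.append((chrom, int(pos), m_case, n_case - m_case, m_ctrl, n_ctrl - m_ctrl))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_cases", "unmeth_cases",
                                     "meth_controls", "unmeth_controls"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene sets


def build_gene_sets(truth: TruthTable, annotation: GenomeAnnotation,
                    config: SimulationConfig, n_random: int = 20) -> dict[str, list[str]]:
    """GMT-style gene sets derived from the planted truth plus random sets."""
    rng = config.rng("genesets")
    sets: dict[str, list[str]] = {}
    for ct in config.cell_types:
        for direction in ("hypo", "hyper"):
            sub = truth.dmrs[(truth.dmrs["cell_type"] == ct)
                             & (truth.dmrs["direction"] == direction)]
            sets[f"planted_{ct}_{direction}"] = sorted(sub["gene_id"])
        hm = truth.hmrs[truth.hmrs["cell_type"] == ct]
        sets[f"hmr_{ct}"] = sorted(hm["gene_id"])
    sets["gwas_locus_genes"] = sorted(
        truth.gwas_membership.loc[truth.gwas_membership["in_locus"], "gene_id"])
    gene_ids = list(annotation.genes["gene_id"])
    for i in range(n_random):
        size = int(rng.integers(10, max(11, len(gene_ids) // 10)))
        sets[f"random_{i:02d}"] = sorted(rng.choice(gene_ids, size=size, replace=False))
    return {k: v for k, v in sets.items() if v}


def default_config(**overrides) -> SimulationConfig:
    """Convenience constructor used by tests and the CLI."""
    return replace(SimulationConfig(), **overrides).validate()


def config_to_dict(config: SimulationConfig) -> dict:
    return {f.name: getattr(config, f.name) for f in fields(SimulationConfig)}
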