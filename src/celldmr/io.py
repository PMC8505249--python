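"""Plain-text readers and writers for every artifact the pipeline exchanges.

Formats: BED (interval tracks; 0-based half-open, noted in a leading comment),
TSV (signal matrix, sample sheet, gene tables), GMT (gene sets) and a
``key: value`` manifest dialect for configs.  Writers are deterministic:
identical in-memory objects produce byte-identical files.
"""

from __future__ import annotations

import ast
import json
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import sort_intervals
from .synthetic_data import (GenomeAnnotation, ProbeLayout, SignalBundle,
                             SimulationConfig, TruthTable, build_gene_sets,
                             config_to_dict)

COORD_COMMENT = "# coordinates: 0-based, half-open [start, end)"


def _write(path: Path, text: str) -> None:
    try:
        path.write_text(text)
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def write_bed(path: Path, df: pd.DataFrame, columns: list[str]) -> None:
    """BED-style file: chrom, start, end plus the named extra columns, sorted."""
    out = sort_intervals(df)
    lines = [COORD_COMMENT]
    for _, row in out.iterrows():
        vals = [str(row["chrom"]), str(int(row["start"])), str(int(row["end"]))]
        vals += [str(row[c]) for c in columns]
        lines.append("\t".join(vals))
    _write(path, "\n".join(lines) + "\n")


def read_bed(path: Path, columns: list[str]) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        rows.append(parts[: 3 + len(columns)])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"] + columns)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_manifest(path: Path, mapping: dict) -> None:
    lines = [f"{k}: {v!r}" for k, v in mapping.items()]
    _write(path, "\n".join(lines) + "\n")


def read_manifest(path: Path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        out[key.strip()] = ast.literal_eval(val.strip())
    return out


def config_from_manifest(path: Path) -> SimulationConfig:
    raw = read_manifest(path)
    known = {f.name for f in fields(SimulationConfig)}
    kwargs = {}
    for k, v in raw.items():
        if k not in known:
            continue
        kwargs[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v) \
            if isinstance(v, list) else v
    return SimulationConfig(**kwargs).validate()


def write_gmt(path: Path, gene_sets: dict) -> None:
    lines = [f"{name}\t{name}\t" + "\t".join(genes)
             for name, genes in sorted(gene_sets.items())]
    _write(path, "\n".join(lines) + "\n")


def read_gmt(path: Path) -> dict:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_tsv(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# fixture round-trip


def write_fixture(annotation: GenomeAnnotation, layout: ProbeLayout,
                  signals: SignalBundle, truth: TruthTable,
                  outdir: Path, config: SimulationConfig) -> list[Path]:
    """Write the complete synthetic study to ``outdir`` as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def reg(name):
        p = outdir / name
        written.append(p)
        return p

    write_manifest(reg("manifest.txt"), config_to_dict(config))
    write_tsv(reg("chromosomes.tsv"),
              pd.DataFrame(annotation.chromosomes, columns=["chrom", "length"]))
    write_tsv(reg("genes.tsv"), annotation.genes)
    write_tsv(reg("gene_features.tsv"), annotation.gene_features)
    write_bed(reg("promoters.bed"), annotation.promoters, ["gene_id"])
    write_bed(reg("cpg_islands.bed"), annotation.cpg_islands, [])
    write_tsv(reg("probes.tsv"), layout.probes)
    write_tsv(reg("signals.tsv"), signals.signals, index=True)
    write_tsv(reg("samples.tsv"), signals.sample_sheet)
    write_tsv(reg("truth_baseline.tsv"), truth.baseline)
    write_bed(reg("truth_dmrs.bed"), truth.dmrs,
              ["direction", "gene_id", "cell_type", "effect_size"])
    write_bed(reg("truth_hmrs.bed"), truth.hmrs, ["gene_id", "cell_type"])
    for cond, sub in truth.drug.groupby("condition"):
        write_bed(reg(f"drug_{cond}.bed"), sub, ["direction", "gene_id", "source"])
    write_bed(reg("gwas_loci.bed"), truth.gwas_loci, ["locus_id", "gene_id"])
    write_tsv(reg("gwas_membership.tsv"), truth.gwas_membership)
    write_gmt(reg("gene_sets.gmt"), build_gene_sets(truth, annotation, config))
    return written


def read_fixture(outdir: Path) -> tuple[GenomeAnnotation, ProbeLayout, SignalBundle,
                                        TruthTable, SimulationConfig]:
    outdir = Path(outdir)
    config = config_from_manifest(outdir / "manifest.txt")
    chroms = pd.read_csv(outdir / "chromosomes.tsv", sep="\t")
    annotation = GenomeAnnotation(
        chromosomes=tuple((r["chrom"], int(r["length"])) for _, r in chroms.iterrows()),
        genes=pd.read_csv(outdir / "genes.tsv", sep="\t"),
        gene_features=pd.read_csv(outdir / "gene_features.tsv", sep="\t"),
        cpg_islands=read_bed(outdir / "cpg_islands.bed", []),
        promoters=read_bed(outdir / "promoters.bed", ["gene_id"]),
    )
    probes = pd.read_csv(outdir / "probes.tsv", sep="\t")
    layout = ProbeLayout(probes=probes, spacing=config.probe_spacing)
    signals = pd.read_csv(outdir / "signals.tsv", sep="\t", index_col="probe_id")
    sheet = pd.read_csv(outdir / "samples.tsv", sep="\t")
    bundle = SignalBundle(signals=signals, sample_sheet=sheet)
    dmrs = read_bed(outdir / "truth_dmrs.bed",
                    ["direction", "gene_id", "cell_type", "effect_size"])
    dmrs["effect_size"] = dmrs["effect_size"].astype(float)
    dmrs = dmrs[["gene_id", "cell_type", "chrom", "start", "end", "direction",
                 "effect_size"]]
    hmrs = read_bed(outdir / "truth_hmrs.bed", ["gene_id", "cell_type"])
    hmrs = hmrs[["gene_id", "cell_type", "chrom", "start", "end"]]
    drug_frames = []
    for p in sorted(outdir.glob("drug_*.bed")):
        cond = p.stem.removeprefix("drug_")
        sub = read_bed(p, ["direction", "gene_id", "source"])
        sub.insert(0, "condition", cond)
        drug_frames.append(sub[["condition", "gene_id", "chrom", "start", "end",
                                "direction", "source"]])
    drug = pd.concat(drug_frames, ignore_index=True) if drug_frames else \
        pd.DataFrame(columns=["condition", "gene_id", "chrom", "start", "end",
                              "direction", "source"])
    loci = read_bed(outdir / "gwas_loci.bed", ["locus_id", "gene_id"])
    loci = loci[["locus_id", "chrom", "start", "end", "gene_id"]]
    truth = TruthTable(
        baseline=pd.read_csv(outdir / "truth_baseline.tsv", sep="\t"),
        dmrs=dmrs, hmrs=hmrs, drug=drug, gwas_loci=loci,
        gwas_membership=pd.read_csv(outdir / "gwas_membership.tsv", sep="\t"),
    )
    return annotation, layout, bundle, truth, config


def write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    _write(Path(path), json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
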