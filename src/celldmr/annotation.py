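"""Genomic-context classification and gene-set enrichment of DMRs.

CpG context follows the island / shore / shelf convention: shores are the 2 kb
regions flanking an island, shelves the next 2 kb beyond the shores, measured
from island boundaries; precedence island > shore > shelf > open sea on a
>=1 bp overlap rule (a midpoint mode is available).  Gene context uses the
precedence promoter > 5'UTR > exon > intron > 3'UTR > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlaps_any
from .stats import fisher_exact_2x2, hypergeom_enrichment_p
from .synthetic_data import GenomeAnnotation

CPG_CONTEXTS = ("island", "shore", "shelf", "open_sea")
GENE_CONTEXTS = ("promoter", "five_prime_utr", "exon", "intron",
                 "three_prime_utr", "intergenic")


def _flanks(track: pd.DataFrame, inner: int, outer: int) -> pd.DataFrame:
    """Intervals [start-outer, start-inner) and [end+inner, end+outer) per row."""
    left = pd.DataFrame({"chrom": track["chrom"],
                         "start": np.maximum(track["start"] - outer, 0),
                         "end": np.maximum(track["start"] - inner, 0)})
    right = pd.DataFrame({"chrom": track["chrom"], "start": track["end"] + inner,
                          "end": track["end"] + outer})
    both = pd.concat([left, right], ignore_index=True)
    return both[both["start"] < both["end"]].reset_index(drop=True)


def _as_points(intervals: pd.DataFrame) -> pd.DataFrame:
    mid = (intervals["start"] + intervals["end"]) // 2
    return pd.DataFrame({"chrom": intervals["chrom"], "start": mid, "end": mid + 1})


def classify_cpg_context(intervals: pd.DataFrame, cpg_islands: pd.DataFrame,
                         flank: int = 2000, midpoint: bool = False) -> pd.Series:
    """Label each interval island / shore / shelf / open_sea.

    Islands are merged (joining touching pieces) before flank construction, so
    fragmenting an island into adjacent pieces cannot change any label.
    """
    islands = merge_intervals(cpg_islands)
    query = _as_points(intervals) if midpoint else intervals
    shore = _flanks(islands, 0, flank)
    shelf = _flanks(islands, flank, 2 * flank)
    labels = np.full(len(query), "open_sea", dtype=object)
    if not islands.empty:
        for name, track in (("shelf", shelf), ("shore", shore), ("island", islands)):
            hit = overlaps_any(query, track)
            labels[hit] = name  # later assignments take precedence
    return pd.Series(labels, index=intervals.index, name="cpg_context")


def classify_gene_context(intervals: pd.DataFrame, annotation: GenomeAnnotation,
                          midpoint: bool = False) -> pd.Series:
    """Label each interval by gene structure with the documented precedence."""
    feats = annotation.gene_features
    spans = annotation.genes.set_index("gene_id")
    for _, row in feats[feats["feature"] == "exon"].iterrows():
        g = spans.loc[row["gene_id"]]
        if not (g["start"] <= row["start"] and row["end"] <= g["end"]):
            raise ValueError(f"malformed gene model: exon of {row['gene_id']} "
                             "outside gene span")
    query = _as_points(intervals) if midpoint else intervals
    labels = np.full(len(query), "intergenic", dtype=object)
    tracks = {
        "three_prime_utr": feats[feats["feature"] == "three_prime_utr"],
        "intron": feats[feats["feature"] == "intron"],
        "exon": feats[feats["feature"] == "exon"],
        "five_prime_utr": feats[feats["feature"] == "five_prime_utr"],
        "promoter": annotation.promoters,
    }
    for name, track in tracks.items():  # ascending precedence; later overwrite
        if track.empty:
            continue
        hit = overlaps_any(query, track[["chrom", "start", "end"]])
        labels[hit] = name
    return pd.Series(labels, index=intervals.index, name="gene_context")


def context_composition_test(labels_a: pd.Series, labels_b: pd.Series,
                             contexts: tuple[str, ...] | None = None,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-context two-sided Fisher test of composition between two DMR sets.

    For each label, the 2x2 table is (in-context vs not) x (set A vs set B).
    No multiplicity correction is applied by default; the significance flag is
    at the given alpha.
    """
    if len(labels_a) == 0 or len(labels_b) == 0:
        raise ValueError("both label sets must be non-empty")
    if contexts is None:
        contexts = tuple(sorted(set(labels_a) | set(labels_b)))
    rows = []
    for ctx in contexts:
        a_in = int((labels_a == ctx).sum())
        b_in = int((labels_b == ctx).sum())
        res = fisher_exact_2x2(a_in, len(labels_a) - a_in, b_in, len(labels_b) - b_in)
        rows.append({"context": ctx, "a_in": a_in, "a_out": len(labels_a) - a_in,
                     "b_in": b_in, "b_out": len(labels_b) - b_in,
                     "odds_ratio": res.odds_ratio, "p_value": res.p_value,
                     "significant": res.p_value < alpha})
    return pd.DataFrame(rows)


@dataclass
class TermEnrichmentResult:
    term: str
    hits: int
    set_size: int
    query_size: int
    background_size: int
    odds_ratio: float
    p_value: float
    member_genes: tuple[str, ...]
    strata_counts: dict
    strata_pct: dict
    neuronal_pct: float  # percentage used for the reported sort order


def term_enrichment(query_genes, background_genes, gene_sets: dict,
                    strata: dict | None = None,
                    sort_stratum: str | None = None) -> list[TermEnrichmentResult]:
    """One-sided (over-representation) Fisher enrichment over GMT gene sets.

    ``strata`` optionally maps each query gene to a stratum label (e.g.
    neuronal / nonneuronal / common); each term then carries the partition of
    its query hits, and results are sorted ascending by the percentage of the
    ``sort_stratum`` (first stratum alphabetically when unset), then by term
    name for reproducibility.  Without strata, results sort by P then term.
    """
    query = set(query_genes)
    background = set(background_genes)
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes missing from background: {offenders[:10]}"
                         + (" ..." if len(offenders) > 10 else ""))
    results = []
    for term, members in gene_sets.items():
        mset = set(members) & background
        if not mset:
            continue
        hit_genes = tuple(sorted(mset & query))
        k, K, n, N = len(hit_genes), len(mset), len(query), len(background)
        p = hypergeom_enrichment_p(k, n, K, N)
        res = fisher_exact_2x2(k, n - k, K - k, N - K - n + k)
        counts: dict[str, int] = {}
        if strata is not None:
            for g in hit_genes:
                s = strata.get(g, "unassigned")
                counts[s] = counts.get(s, 0) + 1
        pct = {s: 100.0 * c / k for s, c in counts.items()} if k else {}
        stratum_keys = sorted(counts) if counts else []
        key = sort_stratum if sort_stratum is not None else \
            (stratum_keys[0] if stratum_keys else "")
        results.append(TermEnrichmentResult(
            term=term, hits=k, set_size=K, query_size=n, background_size=N,
            odds_ratio=res.odds_ratio, p_value=p, member_genes=hit_genes,
            strata_counts=counts, strata_pct=pct,
            neuronal_pct=pct.get(key, 0.0)))
    if strata is not None:
        results.sort(key=lambda r: (r.neuronal_pct, r.term))
    else:
        results.sort(key=lambda r: (r.p_value, r.term))
    return results


def enrichment_table(results: list[TermEnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"term": r.term, "hits": r.hits, "set_size": r.set_size,
               "query_size": r.query_size, "background_size": r.background_size,
               "odds_ratio": r.odds_ratio, "p_value": r.p_value,
               "member_genes": ",".join(r.member_genes)}
        for s, pct in sorted(r.strata_pct.items()):
            row[f"pct_{s}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
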