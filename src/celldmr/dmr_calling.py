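"""Case/control differential methylation: candidate DMRs per replicate
experiment, replicate intersection with direction concordance, and gene
association with cross-cell-type overlap summaries.

The per-probe differential statistic is a Welch t on smoothed window scores;
runs of same-sign probes exceeding the |t| threshold are merged with the same
run/gap/min-probe logic as MR calling.  A DMR is *hyper* when the patient mean
exceeds the control mean, *hypo* otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import intersect_join, merge_intervals, sort_intervals
from .mr_calling import MRParams, _runs_with_gaps, window_scores_matrix
from .synthetic_data import GenomeAnnotation, ProbeLayout, SignalBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DMRParams:
    """Candidate-DMR caller parameters; run/gap logic mirrors MR calling."""

    bandwidth: int = 300
    trim: float = 0.1
    stat_threshold: float = 3.0  # |Welch t| cutoff per probe
    min_probes: int = 4
    max_gap: int = 110

    def validate(self) -> "DMRParams":
        if self.stat_threshold <= 0 or self.min_probes < 1 or self.max_gap < 0:
            raise ValueError("invalid DMR parameters")
        return self


@dataclass
class DMRSet:
    """Differential regions for one cell type (direction = patients vs controls)."""

    cell_type: str
    replicate: str  # "e1", "e2" or "intersect"
    regions: pd.DataFrame  # chrom, start, end, direction, score, p_value, n_probes [, genes]
    discordant: int = 0  # replicate overlaps dropped for direction disagreement

    def __len__(self) -> int:
        return len(self.regions)

    def track(self) -> pd.DataFrame:
        return self.regions[["chrom", "start", "end", "direction"]].copy()


@dataclass
class GeneOverlapSummary:
    """Cross-cell-type gene-level overlap of DMR-associated genes."""

    gene_sets: dict  # (cell_type, direction) -> set of gene ids
    pairwise: pd.DataFrame  # set_a, set_b, n_a, n_b, n_common, pct_of_smaller, pct_of_union
    venn: pd.DataFrame  # direction, only_a, only_b, common (cell-type pair per direction)


# ---------------------------------------------------------------------------


def welch_t(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t statistic and degrees of freedom for (n_probes, n) blocks."""
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1) / n1
    v2 = control.var(axis=1, ddof=1) / n2
    denom = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    t[~np.isfinite(t)] = 0.0
    df[~np.isfinite(df)] = 1.0
    return t, df


def call_candidate_dmrs(signals: SignalBundle, layout: ProbeLayout,
                        cell_type: str, replicate: int,
                        params: DMRParams = DMRParams()) -> DMRSet:
    """Candidate DMRs for one cell type and one replicate experiment."""
    params.validate()
    sheet = signals.sample_columns(cell_type=cell_type, replicate=replicate)
    case_cols = list(sheet.loc[sheet["group"] == "case", "column"])
    ctrl_cols = list(sheet.loc[sheet["group"] == "control", "column"])
    if len(case_cols) < 3 or len(ctrl_cols) < 3:
        raise ValueError(
            f"cell type {cell_type!r} replicate {replicate}: need >=3 samples per group "
            f"(got {len(case_cols)} cases, {len(ctrl_cols)} controls)")
    ref = signals.signals[signals.reference_columns()].to_numpy().mean(axis=1)
    mat = signals.signals[case_cols + ctrl_cols].to_numpy() - ref[:, None]
    scored = window_scores_matrix(mat, layout, params.bandwidth, params.trim)
    t, df = welch_t(scored[:, :len(case_cols)], scored[:, len(case_cols):])

    probes = layout.probes
    gids = probes["gene_id"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()
    rows = []
    bounds = np.flatnonzero(np.r_[True, gids[1:] != gids[:-1], True])
    for a, b in zip(bounds[:-1], bounds[1:]):
        tt = t[a:b]
        for sign in (1.0, -1.0):
            qual = sign * tt >= params.stat_threshold
            for run in _runs_with_gaps(qual, starts[a:b], ends[a:b], params.max_gap):
                if len(run) < params.min_probes:
                    continue
                gi = [a + i for i in run]
                mean_t = float(t[gi].mean())
                mean_df = float(df[gi].mean())
                p = float(2.0 * sps.t.sf(abs(mean_t), mean_df))
                rows.append((chroms[a], int(starts[gi[0]]), int(ends[gi[-1]]),
                             "hyper" if sign > 0 else "hypo", mean_t, p, len(run)))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                          "score", "p_value", "n_probes"])
    regions = sort_intervals(regions)
    return DMRSet(cell_type=cell_type, replicate=f"e{replicate}", regions=regions)


def intersect_replicates(dmrs_exp1: DMRSet, dmrs_exp2: DMRSet) -> DMRSet:
    """Base-pair intersection of same-direction replicate DMRs.

    Opposite-direction overlapping pairs are dropped and counted in
    ``discordant`` (and logged).  Within each direction the intersection
    pieces are merged, so the result is sorted and non-overlapping.
    """
    if dmrs_exp1.cell_type != dmrs_exp2.cell_type:
        raise ValueError(
            f"cell-type mismatch: {dmrs_exp1.cell_type!r} vs {dmrs_exp2.cell_type!r}")
    r1, r2 = dmrs_exp1.regions, dmrs_exp2.regions
    pieces = []
    for direction in ("hyper", "hypo"):
        a = r1[r1["direction"] == direction].reset_index(drop=True)
        b = r2[r2["direction"] == direction].reset_index(drop=True)
        join = intersect_join(a, b)
        for _, row in join.iterrows():
            ra, rb = a.iloc[row["idx_a"]], b.iloc[row["idx_b"]]
            pieces.append((row["chrom"], row["start"], row["end"], direction,
                           float((ra["score"] + rb["score"]) / 2.0),
                           ra["score"], rb["score"], ra["p_value"], rb["p_value"],
                           int(min(ra["n_probes"], rb["n_probes"]))))
    cols = ["chrom", "start", "end", "direction", "score", "score_exp1", "score_exp2",
            "p_exp1", "p_exp2", "n_probes"]
    pieces_df = pd.DataFrame(pieces, columns=cols)
    merged_parts = []
    for direction in ("hyper", "hypo"):
        sub = pieces_df[pieces_df["direction"] == direction]
        if sub.empty:
            continue
        merged = merge_intervals(sub, join_adjacent=False)
        # re-attach per-region evidence: mean over contributing pieces
        keep = []
        for _, m in merged.iterrows():
            contrib = sub[(sub["chrom"] == m["chrom"]) & (sub["start"] < m["end"])
                          & (sub["end"] > m["start"])]
            keep.append({"chrom": m["chrom"], "start": m["start"], "end": m["end"],
                         "direction": direction,
                         "score": float(contrib["score"].mean()),
                         "score_exp1": float(contrib["score_exp1"].mean()),
                         "score_exp2": float(contrib["score_exp2"].mean()),
                         "p_exp1": float(contrib["p_exp1"].mean()),
                         "p_exp2": float(contrib["p_exp2"].mean()),
                         "n_probes": int(contrib["n_probes"].max())})
        merged_parts.append(pd.DataFrame(keep))
    regions = (sort_intervals(pd.concat(merged_parts, ignore_index=True))
               if merged_parts else pd.DataFrame(columns=cols))
    n_discord = 0
    for d1, d2 in (("hyper", "hypo"), ("hypo", "hyper")):
        a = r1[r1["direction"] == d1].reset_index(drop=True)
        b = r2[r2["direction"] == d2].reset_index(drop=True)
        n_discord += len(intersect_join(a, b))
    if n_discord:
        logger.warning("intersect_replicates(%s): dropped %d discordant-direction overlaps",
                       dmrs_exp1.cell_type, n_discord)
    return DMRSet(cell_type=dmrs_exp1.cell_type, replicate="intersect",
                  regions=regions, discordant=n_discord)


def call_dmrs(signals: SignalBundle, layout: ProbeLayout, cell_type: str,
              params: DMRParams = DMRParams(),
              replicates: tuple[int, int] = (1, 2)) -> tuple[DMRSet, DMRSet, DMRSet]:
    """Convenience wrapper: candidates per replicate plus their intersection."""
    d1 = call_candidate_dmrs(signals, layout, cell_type, replicates[0], params)
    d2 = call_candidate_dmrs(signals, layout, cell_type, replicates[1], params)
    return d1, d2, intersect_replicates(d1, d2)


# ---------------------------------------------------------------------------
# gene association


def _associate_one(dmrs: DMRSet, promoters: pd.DataFrame) -> DMRSet:
    regions = dmrs.regions.reset_index(drop=True).copy()
    join = intersect_join(regions, promoters.reset_index(drop=True))
    gene_lists: list[list[str]] = [[] for _ in range(len(regions))]
    for _, row in join.iterrows():
        gene_lists[row["idx_a"]].append(promoters.iloc[row["idx_b"]]["gene_id"])
    regions["genes"] = [",".join(sorted(set(g))) for g in gene_lists]
    return DMRSet(cell_type=dmrs.cell_type, replicate=dmrs.replicate,
                  regions=regions, discordant=dmrs.discordant)


def associate_genes(dmrs_by_cell_type: dict[str, DMRSet],
                    annotation: GenomeAnnotation) -> tuple[dict[str, DMRSet],
                                                           GeneOverlapSummary]:
    """Attach promoter-overlap gene ids (>=1 bp rule) and summarize gene-level
    overlap between cell types.

    Overlap percentage uses the smaller set as denominator (the union-based
    percentage is also reported).  A gene carrying both hyper and hypo DMRs
    appears in both direction sets.
    """
    promoters = annotation.promoters[["chrom", "start", "end", "gene_id"]]
    annotated = {ct: _associate_one(d, promoters) for ct, d in dmrs_by_cell_type.items()}
    gene_sets: dict[tuple[str, str], set] = {}
    for ct, d in annotated.items():
        for direction in ("hyper", "hypo"):
            sub = d.regions[d.regions["direction"] == direction]
            genes = set()
            for gl in sub["genes"]:
                genes.update(g for g in str(gl).split(",") if g)
            gene_sets[(ct, direction)] = genes

    pair_rows, venn_rows = [], []
    keys = sorted(gene_sets)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            a, b = gene_sets[ka], gene_sets[kb]
            common = len(a & b)
            smaller = min(len(a), len(b))
            union = len(a | b)
            pair_rows.append({
                "set_a": "_".join(ka), "set_b": "_".join(kb),
                "n_a": len(a), "n_b": len(b), "n_common": common,
                "pct_of_smaller": 100.0 * common / smaller if smaller else float("nan"),
                "pct_of_union": 100.0 * common / union if union else float("nan"),
            })
    cell_types = sorted({ct for ct, _ in keys})
    if len(cell_types) == 2:
        ct1, ct2 = cell_types
        for direction in ("hyper", "hypo", "all"):
            if direction == "all":
                a = gene_sets[(ct1, "hyper")] | gene_sets[(ct1, "hypo")]
                b = gene_sets[(ct2, "hyper")] | gene_sets[(ct2, "hypo")]
            else:
                a, b = gene_sets[(ct1, direction)], gene_sets[(ct2, direction)]
            venn_rows.append({"direction": direction, "set_a": ct1, "set_b": ct2,
                              "only_a": len(a - b), "only_b": len(b - a),
                              "common": len(a & b)})
    return annotated, GeneOverlapSummary(
        gene_sets={k: v for k, v in gene_sets.items()},
        pairwise=pd.DataFrame(pair_rows),
        venn=pd.DataFrame(venn_rows))
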