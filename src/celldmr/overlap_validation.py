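"""Overlap of DMRs with auxiliary tracks and per-CpG validation.

Covers region-level overlap percentages with drug-induced DMR tracks (per
condition or the union of conditions), directional concordance testing (do
hypomethylated disease DMRs preferentially overlap hypermethylated
drug-induced regions, and vice versa), and RRBS-style validation of DMRs from
pooled per-CpG methylated/unmethylated counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlaps_any
from .stats import FisherResult, fisher_exact_2x2

logger = logging.getLogger(__name__)


@dataclass
class OverlapFractionResult:
    percent: float  # % of DMRs overlapped (union of conditions in any_condition mode)
    per_condition: dict  # condition -> % overlapped (empty in single-track mode)
    flags: pd.DataFrame  # DMR regions + overlap booleans


def overlap_fraction(dmrs: pd.DataFrame, track, mode: str = "any_condition"
                     ) -> OverlapFractionResult:
    """Fraction of DMRs overlapping a track by >=1 bp, at region level.

    ``track`` may be a single interval frame or a mapping of condition name to
    frame.  ``any_condition`` counts a DMR as overlapped if it intersects the
    union of all condition tracks; ``per_condition`` reports each condition
    separately (the ``overlap`` column is then the any-condition flag).
    """
    if len(dmrs) == 0:
        raise ValueError("empty DMR set: overlap percentage undefined")
    if mode not in ("any_condition", "per_condition"):
        raise ValueError(f"unknown mode {mode!r}")
    tracks = track if isinstance(track, dict) else {"track": track}
    flags = dmrs.reset_index(drop=True).copy()
    per_condition = {}
    union = pd.concat([t[["chrom", "start", "end"]] for t in tracks.values()],
                      ignore_index=True)
    any_hit = overlaps_any(flags, union)
    flags["overlap"] = any_hit
    if mode == "per_condition":
        for cond, t in tracks.items():
            hit = overlaps_any(flags, t[["chrom", "start", "end"]])
            flags[f"overlap_{cond}"] = hit
            per_condition[cond] = 100.0 * hit.mean()
    return OverlapFractionResult(percent=100.0 * any_hit.mean(),
                                 per_condition=per_condition, flags=flags)


@dataclass
class ConcordanceResult:
    bd_direction: str  # disease-DMR direction whose overlap is being tested
    track_direction: str  # direction class of the track regions
    table: tuple  # ((bd_dir overlap, bd_dir not), (other_dir overlap, other_dir not))
    odds_ratio: float
    p_value: float
    degenerate: bool
    n_ambiguous: int  # DMRs overlapping both track directions (counted per overlap)
    per_condition: pd.DataFrame  # condition, bd_direction, n_overlap, n_total


def directional_concordance(dmrs: pd.DataFrame, track: pd.DataFrame
                            ) -> list[ConcordanceResult]:
    """Fisher tests of direction-dependent overlap.

    For each track direction t, the 2x2 table contrasts disease-DMR
    directions by overlap with t-direction track regions:
    rows (bd_direction, the other direction), columns (overlaps t, does not).
    An odds ratio > 1 for the pair (hypo, hyper) means hypomethylated disease
    DMRs preferentially overlap hypermethylated track regions.
    """
    for df, name in ((dmrs, "dmrs"), (track, "track")):
        if "direction" not in df.columns:
            raise ValueError(f"{name}: missing 'direction' labels")
    dmrs = dmrs.reset_index(drop=True)
    hits = {}
    for tdir in ("hyper", "hypo"):
        sub = track[track["direction"] == tdir]
        hits[tdir] = overlaps_any(dmrs, sub[["chrom", "start", "end"]]) if len(sub) \
            else np.zeros(len(dmrs), dtype=bool)
    ambiguous = int((hits["hyper"] & hits["hypo"]).sum())
    if ambiguous:
        logger.info("directional_concordance: %d DMRs overlap both track directions "
                    "(counted per overlap, flagged ambiguous)", ambiguous)
    has_cond = "condition" in track.columns
    results = []
    bd_dir_arr = dmrs["direction"].to_numpy()
    for tdir in ("hyper", "hypo"):
        bd_dir = {"hyper": "hypo", "hypo": "hyper"}[tdir]  # expected concordant pair
        is_bd = bd_dir_arr == bd_dir
        a = int((is_bd & hits[tdir]).sum())
        b = int((is_bd & ~hits[tdir]).sum())
        c = int((~is_bd & hits[tdir]).sum())
        d = int((~is_bd & ~hits[tdir]).sum())
        res: FisherResult = fisher_exact_2x2(a, b, c, d)
        cond_rows = []
        if has_cond:
            for cond, csub in track[track["direction"] == tdir].groupby("condition"):
                ch = overlaps_any(dmrs, csub[["chrom", "start", "end"]])
                for bdir in ("hypo", "hyper"):
                    m = bd_dir_arr == bdir
                    cond_rows.append({"condition": cond, "track_direction": tdir,
                                      "bd_direction": bdir,
                                      "n_overlap": int((m & ch).sum()),
                                      "n_total": int(m.sum())})
        results.append(ConcordanceResult(
            bd_direction=bd_dir, track_direction=tdir,
            table=((a, b), (c, d)), odds_ratio=res.odds_ratio, p_value=res.p_value,
            degenerate=res.degenerate, n_ambiguous=ambiguous,
            per_condition=pd.DataFrame(cond_rows)))
    return results


@dataclass
class CpGValidationSummary:
    n_dmrs: int
    n_covered: int  # DMRs with >=1 CpG whose methylation level could be determined
    n_uncovered: int
    n_validated: int  # >=1 CpG with P < alpha and concordant sign
    n_discordant: int  # DMRs whose only significant CpGs contradict the direction
    rate_by_direction: dict  # direction -> % of covered DMRs validated
    mean_meth_diff: float  # mean |case - control| methylation % over validated DMRs
    per_dmr: pd.DataFrame


def cpg_validation(dmrs: pd.DataFrame, cpg_table: pd.DataFrame,
                   alpha: float = 0.05) -> CpGValidationSummary:
    """Validate DMRs against pooled per-CpG counts.

    Per CpG inside a DMR: two-sided Fisher on (methylated, unmethylated) x
    (patients, controls).  A DMR is validated when at least one contained CpG
    is significant at ``alpha`` with a methylation difference whose sign
    matches the DMR direction; significant CpGs of the opposite sign only are
    flagged discordant.  DMRs with no covered CpG are excluded from the
    validation denominator and counted separately.
    """
    required = ["chrom", "pos", "meth_cases", "unmeth_cases",
                "meth_controls", "unmeth_controls"]
    for col in required:
        if col not in cpg_table.columns:
            raise ValueError(f"cpg_table missing column {col!r}")
    cpg = cpg_table.reset_index(drop=True)
    pvals = np.ones(len(cpg))
    diffs = np.zeros(len(cpg))
    for i, row in cpg.iterrows():
        res = fisher_exact_2x2(int(row["meth_cases"]), int(row["unmeth_cases"]),
                               int(row["meth_controls"]), int(row["unmeth_controls"]))
        pvals[i] = res.p_value
        n_case = row["meth_cases"] + row["unmeth_cases"]
        n_ctrl = row["meth_controls"] + row["unmeth_controls"]
        fc = row["meth_cases"] / n_case if n_case else np.nan
        fo = row["meth_controls"] / n_ctrl if n_ctrl else np.nan
        diffs[i] = fc - fo
    by_chrom = {c: sub for c, sub in cpg.groupby("chrom")}
    rows = []
    for _, d in dmrs.reset_index(drop=True).iterrows():
        sub = by_chrom.get(d["chrom"])
        if sub is None:
            idx = np.array([], dtype=int)
        else:
            pos = sub["pos"].to_numpy()
            idx = sub.index.to_numpy()[(pos >= d["start"]) & (pos < d["end"])]
        covered = bool((~np.isnan(diffs[idx])).any()) if len(idx) else False
        sig = idx[(pvals[idx] < alpha)] if len(idx) else idx
        want = 1.0 if d["direction"] == "hyper" else -1.0
        concordant = sig[np.sign(diffs[sig]) == want] if len(sig) else sig
        validated = len(concordant) > 0
        discordant = (not validated) and len(sig) > 0
        mean_diff = float(np.mean(np.abs(diffs[concordant]))) if validated else np.nan
        rows.append({"chrom": d["chrom"], "start": d["start"], "end": d["end"],
                     "direction": d["direction"], "n_cpgs": len(idx),
                     "n_significant": len(sig), "covered": covered,
                     "validated": validated, "discordant": discordant,
                     "mean_abs_diff": mean_diff})
    per_dmr = pd.DataFrame(rows)
    cov = per_dmr[per_dmr["covered"]]
    rate_by_direction = {}
    for direction in ("hypo", "hyper"):
        sub = cov[cov["direction"] == direction]
        rate_by_direction[direction] = (100.0 * sub["validated"].mean()
                                        if len(sub) else float("nan"))
    validated = cov[cov["validated"]]
    mean_meth_diff = (100.0 * float(validated["mean_abs_diff"].mean())
                      if len(validated) else float("nan"))
    n_disc = int(per_dmr["discordant"].sum())
    if n_disc:
        logger.warning("cpg_validation: %d DMRs had only sign-discordant significant "
                       "CpGs", n_disc)
    return CpGValidationSummary(
        n_dmrs=len(per_dmr), n_covered=int(cov.shape[0]),
        n_uncovered=int((~per_dmr["covered"]).sum()),
        n_validated=int(validated.shape[0]), n_discordant=n_disc,
        rate_by_direction=rate_by_direction, mean_meth_diff=mean_meth_diff,
        per_dmr=per_dmr)
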