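"""Genomic interval primitives.

All coordinates throughout the package are 0-based, half-open ``[start, end)``
(BED convention).  Interval collections are plain :class:`pandas.DataFrame`
objects with at least the columns ``chrom`` (str), ``start`` (int) and ``end``
(int); any extra columns are carried along untouched.  Two intervals overlap
iff they share at least one base, i.e. ``a.start < b.end and b.start < a.end``;
touching intervals (``a.end == b.start``) do not overlap but are joined by
:func:`merge_intervals`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


class IntervalError(ValueError):
    """Raised for malformed interval frames."""


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    """Check required columns and start < end; returns the frame unchanged."""
    for col in INTERVAL_COLUMNS:
        if col not in df.columns:
            raise IntervalError(f"{name}: missing column {col!r}")
    if len(df) and not (df["start"].to_numpy() < df["end"].to_numpy()).all():
        raise IntervalError(f"{name}: found interval with start >= end")
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chrom, start, end), resetting the index."""
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, join_adjacent: bool = True) -> pd.DataFrame:
    """Merge overlapping (and, by default, touching) intervals per chromosome.

    Returns a sorted frame with only chrom/start/end columns.
    """
    validate_intervals(df)
    if df.empty:
        return df[INTERVAL_COLUMNS].copy()
    out_chrom, out_start, out_end = [], [], []
    for chrom, sub in sort_intervals(df).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            joined = s <= cur_e if join_adjacent else s < cur_e
            if joined:
                cur_e = max(cur_e, e)
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = s, e
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def overlaps_any(query: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query interval overlap >=1 bp of the track?"""
    validate_intervals(query, "query")
    validate_intervals(track, "track")
    result = np.zeros(len(query), dtype=bool)
    if query.empty or track.empty:
        return result
    merged = merge_intervals(track)
    by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in merged.groupby("chrom", sort=False)}
    q_chrom = query["chrom"].to_numpy()
    q_start = query["start"].to_numpy()
    q_end = query["end"].to_numpy()
    for chrom, (t_start, t_end) in by_chrom.items():
        mask = q_chrom == chrom
        if not mask.any():
            continue
        # merged track is sorted and disjoint, so ends are increasing:
        # the candidate overlapping interval is the last one starting before q_end
        idx = np.searchsorted(t_start, q_end[mask], side="left")
        hit = (idx > 0) & (t_end[np.maximum(idx - 1, 0)] > q_start[mask])
        result[np.flatnonzero(mask)] = hit
    return result


def intersect_join(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All overlapping pairs between two interval frames.

    Returns a frame with columns chrom, start, end (the intersection piece),
    idx_a, idx_b (positional indices into the inputs), sorted by position.
    """
    validate_intervals(a, "a")
    validate_intervals(b, "b")
    rows: list[tuple] = []
    if a.empty or b.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "idx_a", "idx_b"])
    a_idx = np.arange(len(a))
    b_idx = np.arange(len(b))
    a_ord = np.lexsort((a["start"].to_numpy(), a["chrom"].to_numpy()))
    b_ord = np.lexsort((b["start"].to_numpy(), b["chrom"].to_numpy()))
    a_sorted = a.iloc[a_ord]
    b_sorted = b.iloc[b_ord]
    for chrom in sorted(set(a_sorted["chrom"]) & set(b_sorted["chrom"])):
        sa = a_sorted[a_sorted["chrom"] == chrom]
        sb = b_sorted[b_sorted["chrom"] == chrom]
        ia = a_idx[a_ord][a_sorted["chrom"].to_numpy() == chrom]
        ib = b_idx[b_ord][b_sorted["chrom"].to_numpy() == chrom]
        a_s, a_e = sa["start"].to_numpy(), sa["end"].to_numpy()
        b_s, b_e = sb["start"].to_numpy(), sb["end"].to_numpy()
        j0 = 0
        for i in range(len(sa)):
            # advance past b intervals that end before a[i] starts; b intervals
            # are start-sorted but may be overlapping, so only advance while the
            # earliest-start interval cannot overlap anything later
            while j0 < len(sb) and b_e[j0] <= a_s[i] and b_s[j0] <= a_s[i]:
                j0 += 1
            j = j0
            while j < len(sb) and b_s[j] < a_e[i]:
                s = max(a_s[i], b_s[j])
                e = min(a_e[i], b_e[j])
                if s < e:
                    rows.append((chrom, s, e, ia[i], ib[j]))
                j += 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "idx_a", "idx_b"])
    return sort_intervals(out)


def total_coverage(df: pd.DataFrame) -> int:
    """Total number of bases covered (after merging)."""
    merged = merge_intervals(df)
    if merged.empty:
        return 0
    return int((merged["end"] - merged["start"]).sum())
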