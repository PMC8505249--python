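"""Per-sample methylated-region (MR) calling and sample-level statistics.

An MR is a run of probes whose smoothed enrichment score (sample minus
whole-genome-amplified reference) exceeds a per-sample threshold.  Smoothing
is a 10 %-trimmed mean over a fixed genomic bandwidth within the probe's own
promoter tile, which preserves enrichment-peak semantics while staying fully
specified and oracle-testable.  The two technical replicate experiments of a
sample are window-scored independently and averaged before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import MannWhitneyResult, SpearmanResult, mann_whitney, spearman
from .synthetic_data import ProbeLayout, SignalBundle


@dataclass(frozen=True)
class MRParams:
    """Caller parameters.

    bandwidth      genomic half-window in bp for the trimmed-mean smoother
    trim           fraction trimmed from each tail of the window
    threshold      score threshold; with ``robust=True`` it is a robust z
                   (median + threshold * 1.4826 * MAD of the per-sample scores),
                   otherwise an absolute score cutoff
    min_probes     minimum above-threshold probes per region
    max_gap        largest sub-threshold gap (bp between the end of one
                   qualifying probe and the start of the next) bridged
    """

    bandwidth: int = 300
    trim: float = 0.1
    threshold: float = 2.0
    robust: bool = True
    min_probes: int = 4
    max_gap: int = 110

    def validate(self) -> "MRParams":
        if self.bandwidth < 0 or not np.isfinite(self.threshold):
            raise ValueError("bandwidth must be >= 0 and threshold finite")
        if not 0.0 <= self.trim < 0.5:
            raise ValueError("trim must be in [0, 0.5)")
        if self.min_probes < 1 or self.max_gap < 0:
            raise ValueError("min_probes >= 1 and max_gap >= 0 required")
        return self


@dataclass
class MRSet:
    """Called methylated regions for one sample."""

    sample_id: str
    cell_type: str
    regions: pd.DataFrame  # chrom, start, end, score, n_probes

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class MRCountStats:
    counts: pd.DataFrame  # sample_id, cell_type, group, mr_count
    comparisons: pd.DataFrame  # label, group_a, group_b, n_a, n_b, u, p, method, sidedness
    covariate_tests: pd.DataFrame  # cell_type, group_scope, covariate, rho, p, n


# ---------------------------------------------------------------------------
# window scoring


def _tile_window_scores(values: np.ndarray, positions: np.ndarray, bandwidth: int,
                        trim: float) -> np.ndarray:
    """Trimmed-mean smoothing of one tile's (n_probes, n_cols) values.

    The window of probe *i* is every probe *j* on the tile with
    ``|pos_j - pos_i| <= bandwidth``; edge probes use the truncated window.
    """
    n = values.shape[0]
    left = np.searchsorted(positions, positions - bandwidth, side="left")
    right = np.searchsorted(positions, positions + bandwidth, side="right")
    out = np.empty_like(values, dtype=float)
    widths = right - left
    # uniform interior windows: vectorized sliding sort
    if n >= 2:
        interior = widths == widths.max()
        wmax = int(widths.max())
        if interior.any() and wmax <= n:
            g = int(trim * wmax)
            first = int(np.argmax(interior))
            # interior probes form one contiguous block for uniform spacing
            block = np.flatnonzero(interior)
            if len(block) and block[-1] - block[0] + 1 == len(block):
                windows = np.lib.stride_tricks.sliding_window_view(
                    values, wmax, axis=0)  # (n - wmax + 1, n_cols, wmax)
                sel = windows[left[block]]
                sel = np.sort(sel, axis=-1)
                sl = sel[..., g:wmax - g] if g else sel
                out[block] = sl.mean(axis=-1)
                rest = np.flatnonzero(~interior)
            else:
                rest = np.arange(n)
        else:
            rest = np.arange(n)
    else:
        rest = np.arange(n)
    for i in rest:
        w = values[left[i]:right[i]]
        g = int(trim * w.shape[0])
        ws = np.sort(w, axis=0)
        sl = ws[g:w.shape[0] - g] if g else ws
        out[i] = sl.mean(axis=0)
    return out


def window_scores_matrix(values: np.ndarray, layout: ProbeLayout,
                         bandwidth: int = 300, trim: float = 0.1) -> np.ndarray:
    """Window scores for a whole (n_probes, n_cols) matrix, tile by tile."""
    if len(layout) == 0:
        raise ValueError("empty probe layout")
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    out = np.empty_like(values, dtype=float)
    gids = layout.probes["gene_id"].to_numpy()
    starts = layout.probes["start"].to_numpy()
    bounds = np.flatnonzero(np.r_[True, gids[1:] != gids[:-1], True])
    for a, b in zip(bounds[:-1], bounds[1:]):
        out[a:b] = _tile_window_scores(values[a:b], starts[a:b], bandwidth, trim)
    return out[:, 0] if squeeze else out


def score_windows(signals: SignalBundle, layout: ProbeLayout, sample_id: str,
                  params: MRParams = MRParams()) -> np.ndarray:
    """Replicate-averaged window scores (sample minus reference) for one sample."""
    params.validate()
    sheet = signals.sample_sheet
    cols = list(sheet.loc[sheet["sample_id"] == sample_id, "column"])
    if not cols:
        raise KeyError(f"unknown sample id {sample_id!r}")
    ref = signals.signals[signals.reference_columns()].to_numpy().mean(axis=1)
    diffs = signals.signals[cols].to_numpy() - ref[:, None]
    scored = window_scores_matrix(diffs, layout, params.bandwidth, params.trim)
    return scored.mean(axis=1)


# ---------------------------------------------------------------------------
# region calling


def resolve_threshold(scores: np.ndarray, params: MRParams) -> float:
    """Absolute score cutoff: robust z against the per-sample score distribution."""
    if not params.robust:
        return float(params.threshold)
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    return med + params.threshold * 1.4826 * mad


def _runs_with_gaps(qualifying: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                    max_gap: int) -> list[list[int]]:
    """Group qualifying probe indices into runs, bridging gaps <= max_gap bp."""
    idx = np.flatnonzero(qualifying)
    runs: list[list[int]] = []
    for i in idx:
        if runs and starts[i] - ends[runs[-1][-1]] <= max_gap:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    return runs


def call_mrs(window_scores: np.ndarray, layout: ProbeLayout,
             params: MRParams = MRParams(), sample_id: str = "",
             cell_type: str = "") -> MRSet:
    """Merge above-threshold probe runs into methylated regions.

    A region spans the start of its first qualifying probe to the end of its
    last; ``min_probes`` counts qualifying probes only.  Runs never cross
    promoter-tile boundaries.
    """
    params.validate()
    scores = np.asarray(window_scores, dtype=float)
    if scores.shape[0] != len(layout):
        raise ValueError("window_scores length must equal probe count")
    thr = resolve_threshold(scores, params)
    probes = layout.probes
    gids = probes["gene_id"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()
    rows = []
    bounds = np.flatnonzero(np.r_[True, gids[1:] != gids[:-1], True])
    for a, b in zip(bounds[:-1], bounds[1:]):
        qual = scores[a:b] >= thr
        for run in _runs_with_gaps(qual, starts[a:b], ends[a:b], params.max_gap):
            if len(run) < params.min_probes:
                continue
            gi = [a + i for i in run]
            rows.append((chroms[a], int(starts[gi[0]]), int(ends[gi[-1]]),
                         float(scores[gi].mean()), len(run)))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_probes"])
    regions = regions.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return MRSet(sample_id=sample_id, cell_type=cell_type, regions=regions)


def call_sample_mrs(signals: SignalBundle, layout: ProbeLayout,
                    params: MRParams = MRParams()) -> list[MRSet]:
    """Call MRs for every (subject, cell type) sample in the bundle."""
    ref = signals.signals[signals.reference_columns()].to_numpy().mean(axis=1)
    sheet = signals.sample_sheet
    samples = sheet[sheet["group"] != "reference"]
    out = []
    for sample_id, sub in samples.groupby("sample_id", sort=True):
        diffs = signals.signals[list(sub["column"])].to_numpy() - ref[:, None]
        scored = window_scores_matrix(diffs, layout, params.bandwidth, params.trim)
        avg = scored.mean(axis=1)
        out.append(call_mrs(avg, layout, params, sample_id=sample_id,
                            cell_type=str(sub["cell_type"].iloc[0])))
    return out


# ---------------------------------------------------------------------------
# sample-level statistics


DEFAULT_COVARIATES = ("age", "pmi", "ph", "onset", "duration", "antipsychotics")


def mr_count_table(mrsets: list[MRSet], sample_sheet: pd.DataFrame) -> pd.DataFrame:
    meta = (sample_sheet[sample_sheet["group"] != "reference"]
            .drop_duplicates("sample_id").set_index("sample_id"))
    rows = [{"sample_id": m.sample_id, "cell_type": m.cell_type,
             "group": meta.loc[m.sample_id, "group"], "mr_count": len(m)}
            for m in mrsets]
    return pd.DataFrame(rows)


def mr_count_stats(mrsets: list[MRSet], sample_sheet: pd.DataFrame,
                   covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> MRCountStats:
    """MR-count group comparisons (Mann-Whitney, two-sided) and per-covariate
    Spearman correlations, per cell type.

    The four standard comparisons are cell-type contrasts within each group
    and case/control contrasts within each cell type.
    """
    counts = mr_count_table(mrsets, sample_sheet)
    meta = (sample_sheet[sample_sheet["group"] != "reference"]
            .drop_duplicates("sample_id").set_index("sample_id"))
    cell_types = sorted(counts["cell_type"].unique())
    comp_rows = []

    def compare(label: str, a_mask, b_mask, name_a: str, name_b: str):
        a = counts.loc[a_mask, "mr_count"].to_numpy()
        b = counts.loc[b_mask, "mr_count"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"comparison {label!r} needs >=2 samples per group")
        res: MannWhitneyResult = mann_whitney(a, b)
        comp_rows.append({"label": label, "group_a": name_a, "group_b": name_b,
                          "n_a": len(a), "n_b": len(b), "u_statistic": res.u_statistic,
                          "p_value": res.p_value, "method": res.method,
                          "degenerate": res.degenerate, "sidedness": "two-sided"})

    if len(cell_types) == 2:
        ct1, ct2 = cell_types
        for grp in ("control", "case"):
            compare(f"{ct1}_vs_{ct2}_within_{grp}",
                    (counts["cell_type"] == ct1) & (counts["group"] == grp),
                    (counts["cell_type"] == ct2) & (counts["group"] == grp),
                    f"{ct1}/{grp}", f"{ct2}/{grp}")
    for ct in cell_types:
        compare(f"case_vs_control_within_{ct}",
                (counts["cell_type"] == ct) & (counts["group"] == "case"),
                (counts["cell_type"] == ct) & (counts["group"] == "control"),
                f"{ct}/case", f"{ct}/control")

    cov_rows = []
    for ct in cell_types:
        sub = counts[counts["cell_type"] == ct]
        for cov in covariates:
            if cov not in meta.columns:
                continue
            vals = meta.loc[sub["sample_id"], cov].to_numpy(dtype=float)
            res: SpearmanResult = spearman(vals, sub["mr_count"].to_numpy(dtype=float))
            scope = "cases" if cov in ("onset", "duration", "antipsychotics") else "all"
            cov_rows.append({"cell_type": ct, "group_scope": scope, "covariate": cov,
                             "rho": res.rho, "p_value": res.p_value, "n": res.n,
                             "degenerate": res.degenerate})
    return MRCountStats(counts=counts, comparisons=pd.DataFrame(comp_rows),
                        covariate_tests=pd.DataFrame(cov_rows))
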