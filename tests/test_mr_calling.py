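"""MR caller: window smoothing, run/gap merging vs brute-force oracle,
threshold monotonicity, planted-region recovery, and count statistics."""

import numpy as np
import pandas as pd
import pytest

from celldmr.intervals import overlaps_any
from celldmr.mr_calling import (MRParams, call_mrs, call_sample_mrs, mr_count_stats,
                                resolve_threshold, score_windows,
                                window_scores_matrix)
from celldmr.synthetic_data import (ProbeLayout, default_config, generate_annotation,
                                    generate_probe_layout, simulate_signals,
                                    simulate_truth)


def toy_layout(n_probes: int, spacing: int = 35, n_tiles: int = 1) -> ProbeLayout:
    frames = []
    for t in range(n_tiles):
        base = 100_000 * t
        starts = base + np.arange(n_probes) * spacing
        frames.append(pd.DataFrame({
            "probe_id": [f"G{t}:{i:03d}" for i in range(n_probes)],
            "chrom": "chr1", "start": starts, "end": starts + 25,
            "gene_id": f"G{t}"}))
    return ProbeLayout(probes=pd.concat(frames, ignore_index=True), spacing=spacing)


def brute_force_mrs(scores, layout, thr, min_probes, max_gap):
    """Run-length oracle over the thresholded score vector, per tile."""
    probes = layout.probes
    regions = []
    for gid, sub in probes.groupby("gene_id", sort=False):
        run = []
        prev_end = None
        for i in sub.index:
            if scores[i] >= thr:
                if run and probes.loc[i, "start"] - prev_end > max_gap:
                    if len(run) >= min_probes:
                        regions.append((probes.loc[run[0], "start"],
                                        probes.loc[run[-1], "end"]))
                    run = []
                run.append(i)
                prev_end = probes.loc[i, "end"]
        if len(run) >= min_probes:
            regions.append((probes.loc[run[0], "start"], probes.loc[run[-1], "end"]))
    return sorted(regions)


class TestWindowScores:
    def test_constant_signal_scores_constant(self):
        layout = toy_layout(30)
        scores = window_scores_matrix(np.full(30, 3.25), layout)
        assert np.allclose(scores, 3.25)

    def test_spike_trimmed_out_of_eleven_probe_window(self):
        # bandwidth 175 bp at 35 bp spacing -> 11-probe interior windows;
        # 10% trimming cuts one value from each tail, excluding the spike
        layout = toy_layout(21)
        vals = np.zeros(21)
        vals[10] = 100.0
        scores = window_scores_matrix(vals, layout, bandwidth=175, trim=0.1)
        for i in (5, 6, 14, 15):  # flanking probes with full 11-probe windows
            w = vals[max(i - 5, 0):i + 6]
            w = np.sort(w)[1:-1]
            assert scores[i] == pytest.approx(w.mean())
        assert scores[6] == 0.0  # spike dropped by the trim

    def test_bandwidth_below_spacing_returns_own_value(self):
        layout = toy_layout(10)
        vals = np.arange(10, dtype=float)
        scores = window_scores_matrix(vals, layout, bandwidth=10)
        assert np.allclose(scores, vals)

    def test_unknown_sample_raises(self, small_study):
        _, layout, _, signals = small_study
        with pytest.raises(KeyError):
            score_windows(signals, layout, "nobody")


class TestCallMRs:
    def test_all_below_threshold_empty(self):
        layout = toy_layout(50)
        mrs = call_mrs(np.zeros(50), layout, MRParams(threshold=1.0, robust=False))
        assert len(mrs) == 0

    def test_single_block_single_region(self):
        layout = toy_layout(50)
        scores = np.zeros(50)
        scores[10:30] = 5.0
        mrs = call_mrs(scores, layout, MRParams(threshold=1.0, robust=False))
        assert len(mrs) == 1
        region = mrs.regions.iloc[0]
        assert region["start"] == 10 * 35 and region["end"] == 29 * 35 + 25
        assert region["n_probes"] == 20

    def test_gap_rule_splits_and_bridges(self):
        layout = toy_layout(40)
        scores = np.zeros(40)
        scores[5:10] = 5.0
        scores[13:18] = 5.0  # 3 sub-threshold probes: gap = 4*35-25 = 115 bp
        params = MRParams(threshold=1.0, robust=False, max_gap=110)
        assert len(call_mrs(scores, layout, params)) == 2
        bridged = MRParams(threshold=1.0, robust=False, max_gap=115)
        assert len(call_mrs(scores, layout, bridged)) == 1

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            layout = toy_layout(int(rng.integers(4, 40)),
                                n_tiles=int(rng.integers(1, 3)))
            scores = rng.normal(size=len(layout))
            params = MRParams(threshold=float(rng.uniform(-0.5, 1.5)), robust=False,
                              min_probes=int(rng.integers(1, 4)),
                              max_gap=int(rng.choice([0, 40, 110, 200])))
            got = [(r["start"], r["end"]) for _, r in
                   call_mrs(scores, layout, params).regions.iterrows()]
            expected = brute_force_mrs(scores, layout, params.threshold,
                                       params.min_probes, params.max_gap)
            assert sorted(got) == expected

    def test_raising_threshold_never_increases_calls_or_coverage(self):
        rng = np.random.default_rng(8)
        layout = toy_layout(60, n_tiles=3)
        scores = rng.normal(size=len(layout)) + 0.5
        prev_n, prev_bp = np.inf, np.inf
        for thr in (0.0, 0.5, 1.0, 1.5, 2.0):
            mrs = call_mrs(scores, layout, MRParams(threshold=thr, robust=False,
                                                    min_probes=2))
            bp = int((mrs.regions["end"] - mrs.regions["start"]).sum())
            assert len(mrs) <= max(prev_n, len(mrs))  # count can split then drop
            assert bp <= prev_bp
            prev_bp = bp
            prev_n = len(mrs)


class TestRecoveryAndStats:
    def test_planted_methylated_promoters_recovered(self, small_study, small_config):
        # effect >= 3x noise SD planted; >=95% of methylated cores hit an MR
        annotation, layout, truth, signals = small_study
        mrsets = call_sample_mrs(signals, layout)
        ctrl_neuron = [m for m in mrsets if m.cell_type == "neuron"
                       and m.sample_id.startswith("ctrl")]
        base = truth.baseline[(truth.baseline["cell_type"] == "neuron")
                              & truth.baseline["methylated"]]
        cores = base.rename(columns={"core_start": "start", "core_end": "end"})[
            ["chrom", "start", "end"]]
        hits = np.zeros(len(cores))
        for m in ctrl_neuron:
            # cores inactive in a given subject are legitimately absent;
            # aggregate across control samples
            hits += overlaps_any(cores, m.regions)
        recovered = (hits >= 0.5 * len(ctrl_neuron)).mean()
        assert recovered >= 0.95

    def test_null_effect_counts_stable_across_groups(self):
        cfg = default_config(n_genes=80, n_cases=5, n_controls=5, dmr_fraction=0.0,
                             chromosomes=(("chr1", 1_000_000),), gwas_n_loci=10,
                             seed=5)
        ann = generate_annotation(cfg)
        layout = generate_probe_layout(ann, cfg.probe_spacing)
        truth = simulate_truth(ann, cfg)
        signals = simulate_signals(ann, layout, truth, cfg)
        mrsets = call_sample_mrs(signals, layout)
        stats = mr_count_stats(mrsets, signals.sample_sheet)
        null_rows = stats.comparisons[
            stats.comparisons["label"].str.startswith("case_vs_control")]
        assert (null_rows["p_value"] > 0.01).all()

    def test_covariate_equal_to_count_gives_rho_one(self, small_study):
        _, layout, _, signals = small_study
        mrsets = call_sample_mrs(signals, layout)
        stats = mr_count_stats(mrsets, signals.sample_sheet)
        counts = stats.counts
        sheet = signals.sample_sheet.copy()
        counts_by_sample = counts.set_index("sample_id")["mr_count"]
        sheet["echo"] = sheet["sample_id"].map(counts_by_sample)
        echoed = mr_count_stats(mrsets, sheet, covariates=("echo",))
        assert np.allclose(echoed.covariate_tests["rho"], 1.0)

    def test_confounded_covariate_detected(self):
        cfg = default_config(n_genes=120, n_cases=8, n_controls=8,
                             chromosomes=(("chr1", 1_500_000),), gwas_n_loci=10,
                             confound_covariate="age", confound_strength=0.15,
                             core_active_prob=0.7, seed=9)
        ann = generate_annotation(cfg)
        layout = generate_probe_layout(ann, cfg.probe_spacing)
        truth = simulate_truth(ann, cfg)
        signals = simulate_signals(ann, layout, truth, cfg)
        # strict threshold so counts reflect core activity, not noise excursions
        mrsets = call_sample_mrs(signals, layout, MRParams(threshold=4.0))
        stats = mr_count_stats(mrsets, signals.sample_sheet)
        age = stats.covariate_tests[stats.covariate_tests["covariate"] == "age"]
        assert (age["rho"] > 0).all()
        assert (age["p_value"] < 0.05).all()
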