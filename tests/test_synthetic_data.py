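"""Generator contracts: geometry, determinism, planted-structure calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from celldmr.intervals import intersect_join
from celldmr.synthetic_data import (ConfigError, InfeasibleError, SizingError,
                                    default_config, generate_annotation,
                                    generate_probe_layout, simulate_signals,
                                    simulate_truth)


def tiny_config(**kw):
    base = dict(n_genes=100, n_cases=4, n_controls=4,
                chromosomes=(("chr1", 1_000_000), ("chr2", 1_000_000)),
                gwas_n_loci=20, seed=1)
    base.update(kw)
    return default_config(**base)


class TestAnnotation:
    def test_tile_width_forced_by_definition(self):
        ann = generate_annotation(tiny_config())
        widths = ann.promoters["end"] - ann.promoters["start"]
        assert len(ann.promoters) == 100
        assert (widths == 10_000).all()

    def test_minus_strand_tile_mirrors_tss(self):
        ann = generate_annotation(tiny_config())
        tiles = ann.promoters.rename(columns={"start": "tile_start", "end": "tile_end"})
        merged = tiles.merge(ann.genes, on=["gene_id", "chrom"])
        plus = merged[merged["strand"] == "+"]
        minus = merged[merged["strand"] == "-"]
        assert (plus["tss"] - plus["tile_start"] == 7500).all()
        assert (minus["tile_end"] - minus["tss"] == 7500).all()

    def test_determinism_same_seed(self):
        a = generate_annotation(tiny_config())
        b = generate_annotation(tiny_config())
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.cpg_islands, b.cpg_islands)

    def test_overpacked_genome_raises_sizing_error(self):
        with pytest.raises(SizingError):
            generate_annotation(tiny_config(n_genes=10_000,
                                            chromosomes=(("chr1", 1_000_000),)))

    def test_tiles_do_not_overlap(self):
        ann = generate_annotation(tiny_config())
        proms = ann.promoters.reset_index(drop=True)
        join = intersect_join(proms, proms)
        assert (join["idx_a"] == join["idx_b"]).all()


class TestProbeLayout:
    def test_probe_count_per_tile(self):
        ann = generate_annotation(tiny_config())
        layout = generate_probe_layout(ann, 35)
        per_tile = layout.probes.groupby("gene_id").size()
        assert (per_tile == 10_000 // 35).all()  # 285

    def test_wide_spacing_two_probes(self):
        ann = generate_annotation(tiny_config())
        layout = generate_probe_layout(ann, 5000)
        assert (layout.probes.groupby("gene_id").size() == 2).all()

    def test_spacing_below_probe_length_rejected(self):
        ann = generate_annotation(tiny_config())
        with pytest.raises(ConfigError):
            generate_probe_layout(ann, 10)

    def test_probes_stay_inside_tiles(self):
        ann = generate_annotation(tiny_config())
        layout = generate_probe_layout(ann, 35)
        merged = layout.probes.merge(ann.promoters, on=["gene_id", "chrom"],
                                     suffixes=("", "_tile"))
        assert (merged["start"] >= merged["start_tile"]).all()
        assert (merged["end"] <= merged["end_tile"]).all()


class TestTruth:
    def test_direction_mix_matches_configured_fraction(self):
        # aggregated binomial check over seeds: 0.9 hypo at ~30 DMRs/cell-type
        total = hypo = 0
        for seed in range(25):
            cfg = tiny_config(n_genes=200, dmr_fraction=0.15, fraction_hypo=0.9,
                              baseline_meth_prob=(("neuron", 0.6), ("nonneuron", 0.6)),
                              chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000)),
                              seed=seed)
            truth = simulate_truth(generate_annotation(cfg), cfg)
            total += len(truth.dmrs)
            hypo += int((truth.dmrs["direction"] == "hypo").sum())
        sd = np.sqrt(total * 0.9 * 0.1)
        assert abs(hypo - 0.9 * total) < 4 * sd

    def test_null_gwas_placement_independent_of_dmrs(self):
        # enrichment odds 1: pooled truth contingency not significant at 1%
        a = b = c = d = 0
        for seed in range(40):
            cfg = tiny_config(gwas_enrichment_odds=1.0, seed=seed)
            truth = simulate_truth(generate_annotation(cfg), cfg)
            dmr_genes = set(truth.dmrs["gene_id"])
            for _, row in truth.gwas_membership.iterrows():
                is_dmr = row["gene_id"] in dmr_genes
                if row["in_locus"]:
                    a, c = (a + 1, c) if is_dmr else (a, c + 1)
                else:
                    b, d = (b + 1, d) if is_dmr else (b, d + 1)
        _, p, *_ = sps.chi2_contingency([[a, b], [c, d]])
        assert p > 0.01

    def test_zero_concordance_means_no_drug_dmr_overlap(self):
        cfg = tiny_config(drug_concordance_fraction=0.0)
        truth = simulate_truth(generate_annotation(cfg), cfg)
        overlap = intersect_join(truth.drug, truth.dmrs)
        assert overlap.empty

    def test_infeasible_hypo_count_raises(self):
        cfg = tiny_config(dmr_fraction=0.9, fraction_hypo=1.0,
                          baseline_meth_prob=(("neuron", 0.2), ("nonneuron", 0.2)))
        with pytest.raises(InfeasibleError):
            simulate_truth(generate_annotation(cfg), cfg)

    def test_dmr_regions_lie_inside_promoter_tiles(self):
        cfg = tiny_config()
        ann = generate_annotation(cfg)
        truth = simulate_truth(ann, cfg)
        tiles = ann.promoters.set_index("gene_id")
        for _, d in truth.dmrs.iterrows():
            tile = tiles.loc[d["gene_id"]]
            assert tile["start"] <= d["start"] < d["end"] <= tile["end"]


class TestSignals:
    def test_no_noise_no_effect_groups_identical(self):
        cfg = tiny_config(noise_sd=0.0, sample_effect_sd=0.0, effect_sizes=(0.0,),
                          core_active_prob=1.0)
        ann = generate_annotation(cfg)
        layout = generate_probe_layout(ann, cfg.probe_spacing)
        truth = simulate_truth(ann, cfg)
        sig = simulate_signals(ann, layout, truth, cfg)
        sheet = sig.sample_sheet
        case_cols = sheet.loc[sheet["group"] == "case", "column"]
        ctrl_cols = sheet.loc[sheet["group"] == "control", "column"]
        case_mean = sig.signals[list(case_cols)].mean(axis=1)
        ctrl_mean = sig.signals[list(ctrl_cols)].mean(axis=1)
        assert np.allclose(case_mean, ctrl_mean)

    def test_planted_hypo_shift_is_minus_effect_sd_at_covered_probes(self):
        cfg = tiny_config(noise_sd=0.25, sample_effect_sd=0.0, effect_sizes=(2.0,),
                          core_active_prob=1.0)
        # build with zero probe noise but nonzero nominal SD so shift = 2 * 0.25
        cfg_clean = tiny_config(noise_sd=0.0, sample_effect_sd=0.0, effect_sizes=(2.0,),
                                core_active_prob=1.0)
        ann = generate_annotation(cfg)
        layout = generate_probe_layout(ann, cfg.probe_spacing)
        truth = simulate_truth(ann, cfg)
        # noise_sd enters both the noise and the shift; emulate clean signal by
        # regenerating with the same truth but zeroed noise via config override
        sig = simulate_signals(ann, layout, truth, cfg_clean)
        sheet = sig.sample_sheet
        neuron = sheet[(sheet["cell_type"] == "neuron") & (sheet["replicate"] == 1)]
        case_cols = list(neuron.loc[neuron["group"] == "case", "column"])
        ctrl_cols = list(neuron.loc[neuron["group"] == "control", "column"])
        hypo = truth.dmrs[(truth.dmrs["direction"] == "hypo")
                          & (truth.dmrs["cell_type"] == "neuron")].iloc[0]
        probes = layout.probes
        inside = ((probes["gene_id"] == hypo["gene_id"])
                  & (probes["start"] >= hypo["start"] + 25)
                  & (probes["end"] <= hypo["end"] - 25))
        diff = (sig.signals.loc[inside.to_numpy(), case_cols].mean(axis=1)
                - sig.signals.loc[inside.to_numpy(), ctrl_cols].mean(axis=1))
        # cfg_clean has noise_sd 0 => shift min(2*0, level) = 0; instead verify
        # the configured-noise run produces the -2 SD mean shift
        sig2 = simulate_signals(ann, layout, truth, cfg)
        diff2 = (sig2.signals.loc[inside.to_numpy(), case_cols].mean(axis=1)
                 - sig2.signals.loc[inside.to_numpy(), ctrl_cols].mean(axis=1))
        assert diff2.mean() == pytest.approx(-2 * 0.25, abs=0.1)
        assert np.allclose(diff, 0.0)

    def test_regenerated_signals_identical(self):
        cfg = tiny_config(seed=7)
        ann = generate_annotation(cfg)
        layout = generate_probe_layout(ann, cfg.probe_spacing)
        truth = simulate_truth(ann, cfg)
        s1 = simulate_signals(ann, layout, truth, cfg)
        s2 = simulate_signals(ann, layout, truth, cfg)
        pd.testing.assert_frame_equal(s1.signals, s2.signals)
        pd.testing.assert_frame_equal(s1.sample_sheet, s2.sample_sheet)

    def test_replicates_share_sample_effect_but_not_noise(self):
        cfg = tiny_config()
        ann = generate_annotation(cfg)
        layout = generate_probe_layout(ann, cfg.probe_spacing)
        truth = simulate_truth(ann, cfg)
        sig = simulate_signals(ann, layout, truth, cfg)
        e1 = sig.signals["case01_neuron.e1"].to_numpy()
        e2 = sig.signals["case01_neuron.e2"].to_numpy()
        assert not np.allclose(e1, e2)  # independent probe noise
        # replicate difference has ~zero mean (shared biology + sample effect)
        assert abs((e1 - e2).mean()) < 0.01

    def test_case_only_covariates_missing_for_controls(self):
        cfg = tiny_config()
        ann = generate_annotation(cfg)
        layout = generate_probe_layout(ann, cfg.probe_spacing)
        truth = simulate_truth(ann, cfg)
        sheet = simulate_signals(ann, layout, truth, cfg).sample_sheet
        ctrl = sheet[sheet["group"] == "control"]
        case = sheet[sheet["group"] == "case"]
        assert ctrl["onset"].isna().all() and case["onset"].notna().all()
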