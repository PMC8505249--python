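"""DMR calling: direction semantics, replicate intersection (incl. a bedtools
cross-check), gene association, and behavior on null data."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from celldmr.dmr_calling import (DMRParams, DMRSet, associate_genes,
                                 call_candidate_dmrs, call_dmrs,
                                 intersect_replicates)
from celldmr.intervals import overlaps_any
from celldmr.synthetic_data import (default_config, generate_annotation,
                                    generate_probe_layout, simulate_signals,
                                    simulate_truth)


def make_dmrset(rows, cell_type="neuron", replicate="e1") -> DMRSet:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
    df["score"] = np.where(df["direction"] == "hyper", 5.0, -5.0)
    df["p_value"] = 0.001
    df["n_probes"] = 10
    return DMRSet(cell_type=cell_type, replicate=replicate, regions=df)


class TestCandidates:
    def test_planted_hypo_called_with_direction(self, small_study):
        annotation, layout, truth, signals = small_study
        cand = call_candidate_dmrs(signals, layout, "neuron", 1)
        planted = truth.dmr_track("neuron")
        hypo = planted[planted["direction"] == "hypo"]
        hit = overlaps_any(hypo, cand.regions[cand.regions["direction"] == "hypo"])
        assert hit.mean() >= 0.9

    def test_swapping_groups_flips_directions(self, small_study):
        annotation, layout, truth, signals = small_study
        cand = call_candidate_dmrs(signals, layout, "neuron", 1)
        swapped = signals.sample_sheet.copy()
        swapped["group"] = swapped["group"].map(
            {"case": "control", "control": "case", "reference": "reference"})
        sig2 = type(signals)(signals=signals.signals, sample_sheet=swapped)
        cand2 = call_candidate_dmrs(sig2, layout, "neuron", 1)
        a = cand.regions[["chrom", "start", "end"]]
        b = cand2.regions[["chrom", "start", "end"]]
        pd.testing.assert_frame_equal(a, b)
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert list(cand2.regions["direction"]) == \
            [flip[d] for d in cand.regions["direction"]]

    def test_too_few_samples_raises(self, small_study):
        annotation, layout, truth, signals = small_study
        sheet = signals.sample_sheet
        keep = sheet[(sheet["group"] != "case")
                     | (sheet["subject"].isin(["case01", "case02"]))]
        sig2 = type(signals)(signals=signals.signals[list(keep["column"])],
                             sample_sheet=keep)
        with pytest.raises(ValueError, match="neuron"):
            call_candidate_dmrs(sig2, layout, "neuron", 1)


class TestIntersect:
    def test_same_direction_overlap_intersects(self):
        d1 = make_dmrset([("chr1", 100, 200, "hypo")])
        d2 = make_dmrset([("chr1", 150, 250, "hypo")], replicate="e2")
        out = intersect_replicates(d1, d2)
        assert len(out) == 1
        r = out.regions.iloc[0]
        assert (r["start"], r["end"], r["direction"]) == (150, 200, "hypo")

    def test_opposite_direction_overlap_dropped_and_logged(self):
        d1 = make_dmrset([("chr1", 100, 200, "hypo")])
        d2 = make_dmrset([("chr1", 150, 250, "hyper")], replicate="e2")
        out = intersect_replicates(d1, d2)
        assert len(out) == 0 and out.discordant == 1

    def test_cell_type_mismatch_raises(self):
        d1 = make_dmrset([("chr1", 0, 10, "hypo")], cell_type="neuron")
        d2 = make_dmrset([("chr1", 0, 10, "hypo")], cell_type="nonneuron")
        with pytest.raises(ValueError):
            intersect_replicates(d1, d2)

    def test_commutative_against_per_base_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(150):
            def random_set(rep):
                n = int(rng.integers(1, 8))
                starts = np.sort(rng.integers(0, 180, size=n))
                rows = []
                prev = 0
                for s in starts:
                    s = max(int(s), prev)
                    e = s + int(rng.integers(1, 25))
                    rows.append(("chr1", s, e,
                                 str(rng.choice(["hyper", "hypo"]))))
                    prev = e  # keep regions non-overlapping within a set
                return make_dmrset(rows, replicate=rep)

            d1, d2 = random_set("e1"), random_set("e2")
            ab = intersect_replicates(d1, d2)
            ba = intersect_replicates(d2, d1)
            for direction in ("hyper", "hypo"):
                mask = np.zeros((2, 300), dtype=bool)
                for k, d in enumerate((d1, d2)):
                    sub = d.regions[d.regions["direction"] == direction]
                    for _, r in sub.iterrows():
                        mask[k, r["start"]:r["end"]] = True
                expected = mask[0] & mask[1]
                for out in (ab, ba):
                    got = np.zeros(300, dtype=bool)
                    sub = out.regions[out.regions["direction"] == direction]
                    for _, r in sub.iterrows():
                        got[r["start"]:r["end"]] = True
                    assert np.array_equal(got, expected)

    @pytest.mark.skipif(shutil.which("bedtools") is None,
                        reason="bedtools not on PATH")
    def test_matches_bedtools_intersect(self, tmp_path):
        rng = np.random.default_rng(22)
        rows1 = [("chr1", int(s), int(s) + int(rng.integers(5, 40)), "hypo")
                 for s in np.sort(rng.choice(np.arange(0, 2000, 50), 12, replace=False))]
        rows2 = [("chr1", int(s), int(s) + int(rng.integers(5, 40)), "hypo")
                 for s in np.sort(rng.choice(np.arange(0, 2000, 30), 15, replace=False))]
        d1, d2 = make_dmrset(rows1), make_dmrset(rows2, replicate="e2")
        ours = intersect_replicates(d1, d2).regions
        f1, f2 = tmp_path / "a.bed", tmp_path / "b.bed"
        for f, rows in ((f1, rows1), (f2, rows2)):
            f.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e, _ in rows))
        out = subprocess.run(["bedtools", "intersect", "-a", f1, "-b", f2],
                             capture_output=True, text=True, check=True).stdout
        bed = sorted(tuple(line.split("\t")) for line in out.strip().splitlines())
        got = sorted((r["chrom"], str(r["start"]), str(r["end"]))
                     for _, r in ours.iterrows())
        assert got == bed


class TestGenes:
    def test_dmr_in_single_tile_gets_that_gene(self, small_study):
        annotation, *_ = small_study
        tile = annotation.promoters.iloc[0]
        d = make_dmrset([(tile["chrom"], tile["start"] + 100, tile["start"] + 300,
                          "hypo")])
        annotated, _ = associate_genes({"neuron": d}, annotation)
        assert annotated["neuron"].regions.iloc[0]["genes"] == tile["gene_id"]

    def test_dmr_spanning_two_tiles_gets_both_genes(self, small_study):
        annotation, *_ = small_study
        proms = annotation.promoters.sort_values(["chrom", "start"])
        t1, t2 = proms.iloc[0], proms.iloc[1]
        assert t1["chrom"] == t2["chrom"]
        d = make_dmrset([(t1["chrom"], t1["end"] - 100, t2["start"] + 100, "hypo")])
        annotated, _ = associate_genes({"neuron": d}, annotation)
        genes = set(annotated["neuron"].regions.iloc[0]["genes"].split(","))
        assert genes == {t1["gene_id"], t2["gene_id"]}

    def test_identical_sets_overlap_100_percent(self, small_study):
        annotation, *_ = small_study
        tile = annotation.promoters.iloc[0]
        rows = [(tile["chrom"], tile["start"] + 100, tile["start"] + 300, "hypo")]
        d1 = make_dmrset(rows, cell_type="neuron")
        d2 = make_dmrset(rows, cell_type="nonneuron")
        _, summary = associate_genes({"neuron": d1, "nonneuron": d2}, annotation)
        hypo = summary.pairwise[
            (summary.pairwise["set_a"] == "neuron_hypo")
            & (summary.pairwise["set_b"] == "nonneuron_hypo")]
        assert hypo.iloc[0]["pct_of_smaller"] == 100.0
        venn = summary.venn[summary.venn["direction"] == "hypo"].iloc[0]
        assert venn["common"] == 1 and venn["only_a"] == 0 and venn["only_b"] == 0


class TestNullBehavior:
    def test_null_candidate_count_small_and_intersection_shrinks(self):
        """With no planted DMRs, candidates are rare window-noise artifacts and
        replicate intersection removes most of them."""
        singles, inters = [], []
        for seed in range(8):
            cfg = default_config(n_genes=60, n_cases=5, n_controls=5,
                                 dmr_fraction=0.0, gwas_n_loci=10,
                                 chromosomes=(("chr1", 800_000),), seed=100 + seed)
            ann = generate_annotation(cfg)
            layout = generate_probe_layout(ann, cfg.probe_spacing)
            truth = simulate_truth(ann, cfg)
            signals = simulate_signals(ann, layout, truth, cfg)
            e1, e2, inter = call_dmrs(signals, layout, "neuron")
            singles.append(len(e1))
            inters.append(len(inter))
        assert np.median(inters) <= np.median(singles)
        # every false region consumes >= min_probes qualifying probes, so the
        # probe-level false-positive rate bounds the expected region count
        from scipy import stats as sps
        n_probes = 60 * (10_000 // 35)
        p_probe = 2 * sps.t.sf(3.0, df=8)  # Welch t at 5+5 samples
        assert np.mean(singles) <= n_probes * p_probe / 4
        assert np.mean(inters) < np.mean(singles) * 0.25
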