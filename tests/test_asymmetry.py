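"""Occupancy normalization, class asymmetry and weighted methylation."""

import math

import numpy as np
import pandas as pd
import pytest

from asekit import asymmetry
from asekit.core import AllelePair, BinnedTrack, DominanceCall, GeneModel, InputError


def _gene(gid="g1", hap="HA", chrom="chr1", start=1000, end=2000, strand="+"):
    return GeneModel(gid, hap, chrom, start, end, strand,
                     [(start, end)], [(start, end)])


def _track(counts, library_size):
    return BinnedTrack(counts={"chr1": np.asarray(counts)},
                       library_size=library_size)


class TestOccupancy:
    def test_zero_counts_give_zero(self):
        track = _track([0] * 20, library_size=1_000_000)
        assert asymmetry.gene_mark_occupancy(track, _gene(), flank_bp=0) == 0.0

    def test_rpkm_formula(self):
        # 10 reads over a 1-kb gene, library 1e6 -> 10 * 1e9 / (1e6 * 1e3)
        counts = [0] * 20
        counts[5] = 4  # bins 1000-1200
        counts[6] = 3
        counts[7] = 2
        counts[8] = 1
        track = _track(counts, library_size=1_000_000)
        occ = asymmetry.gene_mark_occupancy(track, _gene(), flank_bp=0)
        assert occ == pytest.approx(10.0)

    def test_scale_invariance(self):
        counts = np.arange(20)
        occ1 = asymmetry.gene_mark_occupancy(
            _track(counts, 10_000), _gene(), flank_bp=200
        )
        occ2 = asymmetry.gene_mark_occupancy(
            _track(counts * 2, 20_000), _gene(), flank_bp=200
        )
        assert occ1 == pytest.approx(occ2)

    def test_partial_bins_weighted_by_overlap(self):
        counts = [10] + [0] * 19
        track = _track(counts, library_size=1_000_000)
        gene = _gene(start=100, end=200)  # half of bin 0
        occ = asymmetry.gene_mark_occupancy(track, gene, flank_bp=0)
        assert occ == pytest.approx(5 * 1e9 / (1e6 * 100))

    def test_gene_outside_track_rejected(self):
        track = _track([1] * 5, library_size=100)
        with pytest.raises(InputError):
            asymmetry.gene_mark_occupancy(track, _gene(chrom="chrX"))


def _occ_frames(values_a, values_b, mark="H3K36me3"):
    occ_a = pd.DataFrame(
        [{"gene_id": f"a{i}", "haplotype": "HA", "mark": mark, "occupancy": v}
         for i, v in enumerate(values_a)]
    )
    occ_b = pd.DataFrame(
        [{"gene_id": f"b{i}", "haplotype": "HB", "mark": mark, "occupancy": v}
         for i, v in enumerate(values_b)]
    )
    pairs = [AllelePair(f"L{i}", f"a{i}", f"b{i}") for i in range(len(values_a))]
    return occ_a, occ_b, pairs


class TestAsymmetrySummary:
    def test_identical_occupancies_give_zero_diffs_and_p_one(self):
        occ_a, occ_b, pairs = _occ_frames([5.0] * 6, [5.0] * 6)
        dominance = (
            [DominanceCall(f"L{i}", "HA_gt_HB") for i in range(3)]
            + [DominanceCall(f"L{i}", "HA_eq_HB") for i in range(3, 6)]
        )
        summary = asymmetry.asymmetry_summary(occ_a, occ_b, pairs, dominance)
        gt = summary[summary["dominance"] == "HA_gt_HB"].iloc[0]
        assert gt["median_diff"] == 0.0
        assert gt["p_vs_balanced"] == 1.0

    def test_planted_dominant_enrichment_detected(self, rng):
        base = rng.uniform(4, 6, 40)
        # dominant side carries 8x occupancy for the biased classes
        occ_a_vals = np.concatenate([base[:10] * 8, base[10:20], base[20:]])
        occ_b_vals = np.concatenate([base[:10], base[10:20] * 8, base[20:]])
        occ_a, occ_b, pairs = _occ_frames(occ_a_vals, occ_b_vals)
        dominance = (
            [DominanceCall(f"L{i}", "HA_gt_HB") for i in range(10)]
            + [DominanceCall(f"L{i}", "HA_lt_HB") for i in range(10, 20)]
            + [DominanceCall(f"L{i}", "HA_eq_HB") for i in range(20, 40)]
        )
        summary = asymmetry.asymmetry_summary(occ_a, occ_b, pairs, dominance)
        med = summary.set_index("dominance")["median_diff"]
        assert med["HA_gt_HB"] > 0 and med["HA_lt_HB"] > 0
        assert abs(med["HA_eq_HB"]) < 1e-9
        p = summary.set_index("dominance")["p_vs_balanced"]
        assert p["HA_gt_HB"] < 0.01 and p["HA_lt_HB"] < 0.01

    def test_label_swap_negates_differences(self, rng):
        vals_a = rng.uniform(1, 10, 8)
        vals_b = rng.uniform(1, 10, 8)
        occ_a, occ_b, pairs = _occ_frames(vals_a, vals_b)
        dominance = [DominanceCall(f"L{i}", "HA_eq_HB") for i in range(8)]
        fwd = asymmetry.asymmetry_summary(occ_a, occ_b, pairs, dominance)
        # swap: occupancies exchanged and pair orientation flipped
        occ_a2, occ_b2, _ = _occ_frames(vals_b, vals_a)
        swapped = [AllelePair(f"L{i}", f"a{i}", f"b{i}") for i in range(8)]
        rev = asymmetry.asymmetry_summary(occ_a2, occ_b2, swapped, dominance)
        f = fwd.set_index("dominance")["median_diff"]["HA_eq_HB"]
        r = rev.set_index("dominance")["median_diff"]["HA_eq_HB"]
        assert f == pytest.approx(-r)

    def test_generator_planted_enrichment_on_dominant_side(self):
        from asekit import ase
        from asekit.io import sample_metadata
        from asekit.simulate import (
            SimulationConfig, generate_haplotype_pair, simulate_expression,
            simulate_marks,
        )

        config = SimulationConfig(
            n_chromosome_pairs=1, n_loci_per_chromosome=150, seed=19,
            state_signal_lambda=0.0,  # isolate the ASE-coupled component
        )
        genes_a, genes_b, _, _, _, truth = generate_haplotype_pair(config)
        counts, lengths = simulate_expression(config, truth)
        tracks, _ = simulate_marks(config, truth, genes_a, genes_b)
        tpm = ase.normalize(counts, lengths)
        meta = sample_metadata(list(counts.columns))
        pairs = [AllelePair(k, *truth.allele_map[k])
                 for k in sorted(truth.allele_map)]
        calls = []
        for tissue in config.tissues:
            calls += ase.classify_allelic_bias(pairs, tpm, meta, tissue)
        dominance, _ = ase.aggregate_asegs(calls)
        occ_a = asymmetry.occupancy_table(
            {"H3K36me3": tracks["HA"]["H3K36me3"]}, genes_a, flank_bp=0
        )
        occ_b = asymmetry.occupancy_table(
            {"H3K36me3": tracks["HB"]["H3K36me3"]}, genes_b, flank_bp=0
        )
        summary = asymmetry.asymmetry_summary(occ_a, occ_b, pairs, dominance)
        med = summary.set_index("dominance")["median_diff"]
        scale = np.concatenate([occ_a["occupancy"], occ_b["occupancy"]]).mean()
        assert med["HA_gt_HB"] > 0 and med["HA_lt_HB"] > 0
        assert abs(med["HA_eq_HB"]) < 0.2 * scale

    def test_small_class_flagged_insufficient(self):
        occ_a, occ_b, pairs = _occ_frames([1.0], [2.0])
        dominance = [DominanceCall("L0", "HA_gt_HB")]
        summary = asymmetry.asymmetry_summary(occ_a, occ_b, pairs, dominance)
        row = summary[summary["dominance"] == "HA_gt_HB"].iloc[0]
        assert bool(row["insufficient"])


class TestMethylationLevel:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "count_methylated",
                           "count_unmethylated", "context", "trinucleotide"],
        )

    def test_weighted_formula(self):
        rec = self._records([
            ("chr1", 10, "+", 5, 5, "CG", "CGG"),
            ("chr1", 20, "+", 0, 10, "CG", "CGG"),
        ])
        assert asymmetry.weighted_methylation_level(rec) == pytest.approx(0.25)

    def test_fully_methylated_is_one(self):
        rec = self._records([("chr1", 10, "+", 7, 0, "CHH", "CAT")])
        assert asymmetry.weighted_methylation_level(rec) == 1.0

    def test_zero_coverage_sites_excluded(self):
        rec = self._records([
            ("chr1", 10, "+", 0, 0, "CG", "CGG"),
            ("chr1", 20, "+", 3, 1, "CG", "CGG"),
        ])
        assert asymmetry.weighted_methylation_level(rec) == pytest.approx(0.75)

    def test_no_covered_sites_is_nan(self):
        rec = self._records([("chr1", 10, "+", 0, 0, "CG", "CGG")])
        assert math.isnan(asymmetry.weighted_methylation_level(rec))

    def test_region_and_context_filters(self):
        rec = self._records([
            ("chr1", 10, "+", 10, 0, "CG", "CGG"),
            ("chr1", 500, "+", 0, 10, "CG", "CGG"),
            ("chr1", 10, "-", 0, 10, "CHH", "CAT"),
        ])
        level = asymmetry.weighted_methylation_level(
            rec, region=("chr1", 0, 100), context="CG"
        )
        assert level == 1.0
        with pytest.raises(InputError):
            asymmetry.weighted_methylation_level(rec, context="CHX")

    def test_level_bounded_by_per_site_extremes(self, rng):
        rows = []
        for i in range(50):
            cov = int(rng.integers(1, 30))
            meth = int(rng.integers(0, cov + 1))
            rows.append(("chr1", i + 1, "+", meth, cov - meth, "CG", "CGG"))
        rec = self._records(rows)
        per_site = rec["count_methylated"] / (
            rec["count_methylated"] + rec["count_unmethylated"]
        )
        level = asymmetry.weighted_methylation_level(rec)
        assert per_site.min() <= level <= per_site.max()
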