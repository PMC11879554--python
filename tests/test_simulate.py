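"""Generator contracts: counts, determinism, planted effects, round-trips."""

import numpy as np
import pandas as pd
import pytest

from asekit import io as aio
from asekit.core import ConfigurationError
from asekit.simulate import (
    GroundTruth,
    SimulationConfig,
    default_chromatin_truth,
    generate_haplotype_pair,
    simulate_all,
    simulate_expression,
    simulate_marks,
    simulate_metabolome,
    simulate_methylation,
)


def test_locus_counts_forced_by_parameters(small_genome):
    truth = small_genome["truth"]
    assert len(truth.allele_map) == 80
    assert len(truth.unique_genes["HA"]) + len(truth.unique_genes["HB"]) == 20


def test_invalid_configurations_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_loci_per_chromosome=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(nb_dispersion=0.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(bias_fractions={"no_bias": 0.5, "smaller": 0.2,
                                         "larger": 0.2, "largest": 0.2})
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_replicates=1)


def test_planted_fraction_recovery(small_genome):
    config = small_genome["config"]
    fractions = small_genome["truth"].category_fractions()
    tol = 1.0 / len(small_genome["truth"].bias)
    for cat, want in config.bias_fractions.items():
        assert abs(fractions[cat] - want) <= tol


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    config = SimulationConfig(
        n_chromosome_pairs=1, n_loci_per_chromosome=10, n_metabolites=30,
        n_up_metabolites=5, n_down_metabolites=5, seed=42,
    )
    paths1 = simulate_all(config, tmp_path / "run1")
    paths2 = simulate_all(config, tmp_path / "run2")
    for name in paths1:
        assert paths1[name].read_bytes() == paths2[name].read_bytes(), name


def test_outputs_round_trip_through_package_readers(tmp_path):
    config = SimulationConfig(
        n_chromosome_pairs=1, n_loci_per_chromosome=8, n_metabolites=20,
        n_up_metabolites=4, n_down_metabolites=4, seed=5,
    )
    paths = simulate_all(config, tmp_path)
    genes = aio.read_gff3(paths["genes_HA.gff3"])
    assert all(g.cds and g.exons for g in genes)
    cds = aio.read_fasta(paths["cds_HA.fasta"])
    assert set(cds) == {g.gene_id for g in genes}
    blocks = aio.read_synteny(paths["synteny.tsv"])
    assert blocks[0].anchor_pairs
    counts = aio.read_counts(paths["counts.tsv"])
    assert counts.shape[1] == config.n_tissues * config.n_replicates
    track = aio.read_bedgraph(paths["chip_HA_H3K36me3.bedgraph"])
    assert track.chrom_length("HA_chr1") == config.n_loci_per_chromosome * \
        config.gene_spacing + 2000 + (-(config.n_loci_per_chromosome *
                                        config.gene_spacing + 2000)) % 200
    meth = aio.read_cytosine_report(paths["methylation_HB.tsv"])
    assert set(meth["context"].unique()) <= {"CG", "CHG", "CHH"}
    inten, groups = aio.read_metabolite_table(paths["metabolites.tsv"])
    assert inten.shape == (20, 6) and set(groups) == {"leaf", "root"}
    truth = GroundTruth.from_json(paths["ground_truth.json"])
    assert truth.allele_map and truth.planted_dams


class TestExpression:
    def test_planted_ratio_means(self):
        config = SimulationConfig(
            n_chromosome_pairs=1, n_loci_per_chromosome=400,
            allelic_fraction=1.0, tissue_sigma=0.0, n_tissues=2, seed=9,
            bias_fractions={"no_bias": 0.4, "smaller": 0.1, "larger": 0.1,
                            "largest": 0.4},
        )
        _, _, _, _, _, truth = generate_haplotype_pair(config)
        counts, _ = simulate_expression(config, truth)
        ratios = {"no_bias": [], "largest": []}
        for locus, (ga, gb) in truth.allele_map.items():
            cat, direction = truth.bias[locus]
            if cat not in ratios:
                continue
            a, b = counts.loc[ga].mean(), counts.loc[gb].mean()
            if direction == "HB":
                a, b = b, a
            if b > 0:
                ratios[cat].append(a / b)
        assert np.mean(ratios["no_bias"]) == pytest.approx(1.0, abs=0.1)
        # largest category plants a fold change of at least 8
        assert np.mean(ratios["largest"]) >= 8 * 0.85

    def test_zero_base_mean_gives_all_zero_counts(self):
        config = SimulationConfig(
            n_chromosome_pairs=1, n_loci_per_chromosome=5, base_mean=0.0, seed=1
        )
        _, _, _, _, _, truth = generate_haplotype_pair(config)
        counts, _ = simulate_expression(config, truth)
        assert (counts.to_numpy() == 0).all()


class TestMarks:
    def test_dominant_gene_body_enrichment_ratio(self):
        # near-silent chromatin states isolate the ASE-coupled enrichment
        config = SimulationConfig(
            n_chromosome_pairs=1, n_loci_per_chromosome=60,
            allelic_fraction=1.0, seed=21,
            bias_fractions={"no_bias": 0.0, "smaller": 0.0, "larger": 0.0,
                            "largest": 1.0},
            lambda_background=1.0, ase_enrichment=8.0, state_signal_lambda=0.0,
        )
        genes_a, genes_b, _, _, _, truth = generate_haplotype_pair(config)
        tracks, _ = simulate_marks(config, truth, genes_a, genes_b)
        w = config.bin_width
        dom_bins, rec_bins = [], []
        gene_index = {g.gene_id: g for g in genes_a + genes_b}
        for locus, (ga, gb) in truth.allele_map.items():
            _, direction = truth.bias[locus]
            dom, rec = (ga, gb) if direction == "HA" else (gb, ga)
            for gid, sink in ((dom, dom_bins), (rec, rec_bins)):
                g = gene_index[gid]
                arr = tracks[g.haplotype]["H3K36me3"].counts[g.chrom]
                sink.extend(arr[g.start // w : g.end // w])
        ratio = np.mean(dom_bins) / np.mean(rec_bins)
        assert ratio == pytest.approx(8.0, rel=0.2)
        assert len(dom_bins) >= 50

    def test_identity_transition_truth_gives_constant_paths(self):
        marks = ["H3K4me3", "H3K36me3"]
        model = default_chromatin_truth(marks, K=2)
        model.transition = np.eye(2)
        config = SimulationConfig(
            n_chromosome_pairs=2, n_loci_per_chromosome=5,
            mark_names=marks, hmm_truth=model, seed=2,
        )
        genes_a, genes_b, _, _, _, truth = generate_haplotype_pair(config)
        simulate_marks(config, truth, genes_a, genes_b)
        for path in truth.state_paths.values():
            assert len(set(path)) == 1

    def test_control_uncorrelated_with_marks(self):
        config = SimulationConfig(
            n_chromosome_pairs=1, n_loci_per_chromosome=700, seed=3
        )
        genes_a, genes_b, _, _, _, truth = generate_haplotype_pair(config)
        tracks, controls = simulate_marks(config, truth, genes_a, genes_b)
        ctrl = controls["HA"].counts["HA_chr1"].astype(float)
        assert len(ctrl) >= 10_000
        for mark in ("H3K9me2", "H3K36me3"):
            sig = tracks["HA"][mark].counts["HA_chr1"].astype(float)
            assert abs(np.corrcoef(ctrl, sig)[0, 1]) <= 0.1

    def test_non_200bp_bins_rejected(self, small_genome):
        config = SimulationConfig(bin_width=100)
        with pytest.raises(ConfigurationError):
            simulate_marks(
                config, small_genome["truth"], small_genome["genes_a"],
                small_genome["genes_b"],
            )


class TestMethylation:
    def test_context_levels_near_beta_means(self):
        from asekit.asymmetry import weighted_methylation_level

        config = SimulationConfig(
            n_chromosome_pairs=1, n_loci_per_chromosome=500, seed=4
        )
        _, _, _, _, _, truth = generate_haplotype_pair(config)
        reports = simulate_methylation(config, truth)
        rep = reports["HA"]
        assert len(rep) >= 1e4
        assert 0.78 <= weighted_methylation_level(rep, context="CG") <= 0.84
        assert 0.50 <= weighted_methylation_level(rep, context="CHG") <= 0.59
        assert 0.08 <= weighted_methylation_level(rep, context="CHH") <= 0.13

    def test_point_mass_beta_gives_exact_zero(self, small_genome):
        from asekit.asymmetry import weighted_methylation_level

        config = SimulationConfig(
            n_chromosome_pairs=1, n_loci_per_chromosome=20, seed=6,
            methylation_beta_params={"CG": (0.0, 1.0), "CHG": (0.0, 1.0),
                                     "CHH": (0.0, 1.0)},
        )
        _, _, _, _, _, truth = generate_haplotype_pair(config)
        rep = simulate_methylation(config, truth)["HA"]
        assert weighted_methylation_level(rep) == 0.0

    def test_per_site_levels_bounded(self, small_genome):
        config = small_genome["config"]
        rep = simulate_methylation(config, small_genome["truth"])["HB"]
        cov = rep["count_methylated"] + rep["count_unmethylated"]
        level = rep.loc[cov > 0, "count_methylated"] / cov[cov > 0]
        assert ((level >= 0) & (level <= 1)).all()


class TestMetabolome:
    def test_planted_up_metabolites_exceed_fold_threshold(self):
        config = SimulationConfig(seed=8)
        truth = GroundTruth({}, {"HA": [], "HB": []}, {}, {}, {})
        inten, groups = simulate_metabolome(config, truth)
        leaf = inten.loc[:, groups == "leaf"].mean(axis=1)
        root = inten.loc[:, groups == "root"].mean(axis=1)
        l2fc = np.log2(leaf / root)
        up = [m for m, s in truth.planted_dams.items() if s == "up"]
        null = [m for m, s in truth.planted_dams.items() if s == "null"]
        assert len(up) == 200
        assert (l2fc[up] >= 1).mean() >= 0.95
        assert abs(l2fc[null].mean()) < 0.1

    def test_small_noise_gives_tight_replicate_correlation(self):
        config = SimulationConfig(metabolite_noise_sd=0.05, seed=8)
        inten, groups = simulate_metabolome(config)
        logi = np.log2(inten)
        r = np.corrcoef(logi["leaf_1"], logi["leaf_2"])[0, 1]
        assert r > 0.95
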