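"""Binarization, Baum-Welch fitting, decoding and state enrichment."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from asekit.chromatin import (
    BinaryChromatinMatrix,
    ChromatinStateModel,
    binarize_bins,
    decode_states,
    fit_chromatin_hmm,
    model_selection_sweep,
    sample_hmm,
    state_feature_enrichment,
    state_posteriors,
)
from asekit.core import BinnedTrack, InputError
from asekit.simulate import default_chromatin_truth

from .oracles import poisson_upper_tail

MARKS5 = ["H3K4me3", "H3K36me3", "H3K36me2", "H3K9me2", "H3K27me3"]


def _track(counts, library_size=None):
    return BinnedTrack(counts={"chr1": np.asarray(counts)},
                       library_size=library_size)


class TestBinarize:
    def test_all_zero_track_is_all_absent(self):
        calls = binarize_bins(_track([0] * 50))
        assert not calls["chr1"].any()

    def test_poisson_threshold_against_pmf_oracle(self):
        # lambda = 2: count 10 crosses p < 1e-4, count 9 does not
        assert poisson_upper_tail(10, 2.0) < 1e-4 < poisson_upper_tail(9, 2.0)
        mark = _track([9, 10], library_size=100)
        ctrl = _track([2, 2], library_size=100)
        calls = binarize_bins(mark, ctrl)
        assert calls["chr1"].tolist() == [0, 1]

    def test_matches_oracle_across_counts_and_scalings(self):
        lam = 3.0
        counts = np.arange(0, 30)
        mark = _track(counts, library_size=300)
        ctrl = _track([3] * len(counts), library_size=300)
        calls = binarize_bins(mark, ctrl)["chr1"]
        expected = np.array(
            [poisson_upper_tail(c, lam) < 1e-4 for c in counts], dtype=np.int8
        )
        assert (calls == expected).all()
        # doubling counts and expectation jointly shifts calls only through
        # Poisson discreteness; verify directly against the oracle
        mark2 = _track(counts * 2, library_size=600)
        ctrl2 = _track([6] * len(counts), library_size=600)
        calls2 = binarize_bins(mark2, ctrl2)["chr1"]
        expected2 = np.array(
            [poisson_upper_tail(2 * c, 6.0) < 1e-4 for c in counts], dtype=np.int8
        )
        assert (calls2 == expected2).all()

    def test_mismatched_grids_rejected(self):
        with pytest.raises(InputError):
            binarize_bins(_track([1, 2, 3]), _track([1, 2]))


class TestFit:
    def test_single_state_emission_is_column_mean(self, rng):
        X = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(np.int8)
        mat = BinaryChromatinMatrix({"chr1": X}, ["a", "b", "c"])
        model = fit_chromatin_hmm(mat, K=1, seed=0)
        assert np.allclose(model.emission[0], X.mean(axis=0), atol=1e-9)

    def test_log_likelihood_trace_non_decreasing(self, rng):
        truth = default_chromatin_truth(MARKS5, K=4)
        X, _ = sample_hmm(truth, 3000, rng)
        mat = BinaryChromatinMatrix({"chr1": X}, MARKS5)
        model = fit_chromatin_hmm(mat, K=4, seed=1, max_iter=40)
        assert np.all(np.diff(model.log_likelihood_trace) >= -1e-8)

    def test_row_stochasticity_preserved(self, rng):
        truth = default_chromatin_truth(MARKS5, K=4)
        X, _ = sample_hmm(truth, 2000, rng)
        mat = BinaryChromatinMatrix({"chr1": X}, MARKS5)
        model = fit_chromatin_hmm(mat, K=3, seed=0, max_iter=25)
        assert np.allclose(model.transition.sum(axis=1), 1.0, atol=1e-9)
        assert np.isclose(model.initial.sum(), 1.0, atol=1e-9)

    def test_emission_recovery_from_known_model(self, rng):
        truth = default_chromatin_truth(MARKS5, K=4)
        X, _ = sample_hmm(truth, 12_000, rng)
        mat = BinaryChromatinMatrix({"chr1": X}, MARKS5)
        model = fit_chromatin_hmm(mat, K=4, seed=0, max_iter=100)
        cost = np.abs(model.emission[:, None, :] - truth.emission[None]).sum(-1)
        rows, cols = linear_sum_assignment(cost)
        err = np.abs(model.emission[rows] - truth.emission[cols]).max()
        assert err <= 0.05

    def test_more_states_than_bins_rejected(self):
        mat = BinaryChromatinMatrix({"chr1": np.zeros((3, 2), dtype=np.int8)},
                                    ["a", "b"])
        with pytest.raises(InputError):
            fit_chromatin_hmm(mat, K=5)


class TestDecode:
    def test_single_state_covers_everything(self, rng):
        X = (rng.random((100, 2)) < 0.3).astype(np.int8)
        mat = BinaryChromatinMatrix({"chr1": X}, ["a", "b"])
        model = fit_chromatin_hmm(mat, K=1, seed=0)
        seg = decode_states(model, mat)
        assert (seg.labels["chr1"] == 0).all()
        assert seg.coverage[0] == 1.0

    def test_posteriors_sum_to_one(self, rng):
        truth = default_chromatin_truth(MARKS5, K=4)
        X, _ = sample_hmm(truth, 1000, rng)
        gamma = state_posteriors(truth, X)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_emissions_recover_generating_path(self, rng):
        model = ChromatinStateModel(
            K=2, mark_names=["a", "b"],
            emission=np.array([[1.0, 0.0], [0.0, 1.0]]),
            transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
            initial=np.array([0.5, 0.5]),
        )
        X, path = sample_hmm(model, 500, rng)
        mat = BinaryChromatinMatrix({"chr1": X}, ["a", "b"])
        seg = decode_states(model, mat)
        assert (seg.labels["chr1"] == path).all()

    def test_uniform_model_ties_break_to_first_state(self):
        model = ChromatinStateModel(
            K=3, mark_names=["a"],
            emission=np.full((3, 1), 0.5),
            transition=np.full((3, 3), 1 / 3),
            initial=np.full(3, 1 / 3),
        )
        X = np.ones((10, 1), dtype=np.int8)
        seg = decode_states(model, BinaryChromatinMatrix({"chr1": X}, ["a"]))
        assert (seg.labels["chr1"] == 0).all()

    def test_mark_set_mismatch_rejected(self, rng):
        model = default_chromatin_truth(MARKS5, K=2)
        mat = BinaryChromatinMatrix(
            {"chr1": np.zeros((5, 2), dtype=np.int8)}, ["x", "y"]
        )
        with pytest.raises(InputError):
            decode_states(model, mat)

    def test_planted_state_coverage_recovered(self, rng):
        truth = default_chromatin_truth(MARKS5, K=4)
        X, path = sample_hmm(truth, 20_000, rng)
        mat = BinaryChromatinMatrix({"chr1": X}, MARKS5)
        model = fit_chromatin_hmm(mat, K=4, seed=0, max_iter=100)
        seg = decode_states(model, mat)
        true_cov = np.bincount(path, minlength=4) / len(path)
        # match decoded states to generator states by emission distance
        cost = np.abs(model.emission[:, None, :] - truth.emission[None]).sum(-1)
        rows, cols = linear_sum_assignment(cost)
        decoded = seg.coverage[rows]
        assert np.abs(decoded - true_cov[cols]).max() <= 0.02


class TestEnrichment:
    def _segmentation(self):
        labels = np.zeros(1000, dtype=np.int64)
        labels[:100] = 1  # state 1 covers bins 0..99
        from asekit.chromatin import Segmentation

        cov = np.bincount(labels, minlength=2) / 1000
        return Segmentation(labels={"chr1": labels}, coverage=cov[::-1][::-1],
                            bin_width=200)

    def test_exact_overlap_enrichment(self):
        seg = self._segmentation()
        feature = [("chr1", 0, 100 * 200)]
        fe = state_feature_enrichment(seg, feature, genome_size=1000 * 200)
        assert fe[1] == pytest.approx(10.0)
        assert fe[0] == pytest.approx(0.0)

    def test_genome_wide_feature_is_unit_enrichment(self):
        seg = self._segmentation()
        fe = state_feature_enrichment(
            seg, [("chr1", 0, 1000 * 200)], genome_size=1000 * 200
        )
        assert np.allclose(fe, 1.0)


def test_model_selection_sweep_reports_bic(rng):
    truth = default_chromatin_truth(MARKS5, K=4)
    X, _ = sample_hmm(truth, 2000, rng)
    mat = BinaryChromatinMatrix({"chr1": X}, MARKS5)
    sweep = model_selection_sweep(mat, k_values=(2, 3, 4), seed=0,
                                  max_iter=15, tol=1e-1)
    assert list(sweep["K"]) == [2, 3, 4]
    assert sweep["log_likelihood"].is_monotonic_increasing
    assert sweep["bic"].notna().all()
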