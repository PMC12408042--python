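"""Reassembly, imputation pass-through, and MAF-binned evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

import biunet as b
from biunet.genotype_io import MISSING, dosage_of_codes
from biunet.inference_eval import (ImputationResult, mask_matrix,
                                   PredictionTensor)
from biunet.loss import CLASS_DOSAGE
from biunet.segmentation import _window_starts

from conftest import make_matrix, random_matrix


def brute_force_reassemble(probs, segments):
    """Per-site enumeration of every covering window; max winning probability,
    earlier window on ties."""
    cfg = segments.config
    n_snps = segments.n_snps_original
    n_samples = segments.n_samples
    n_win = segments.segments_per_sample
    L = cfg.segment_length
    p = probs.reshape(n_samples, n_win, 4, L)
    starts = _window_starts(n_snps, cfg)
    cls = np.zeros((n_samples, n_snps), dtype=np.uint8)
    prob = np.zeros((n_samples, n_snps))
    dhat = np.zeros((n_samples, n_snps))
    for s in range(n_samples):
        for j in range(n_snps):
            best = (-1.0, None, None)
            for w, start in enumerate(starts):
                off = j - start
                if 0 <= off < L and j < n_snps:
                    vec = p[s, w, :, off]
                    mp = vec.max()
                    if mp > best[0]:
                        best = (mp, int(vec.argmax()) + 1, float(vec @ CLASS_DOSAGE))
            prob[s, j], cls[s, j], dhat[s, j] = best[0], best[1], best[2]
    return cls, prob, dhat


def random_predictions(rng, segments):
    return PredictionTensor(b.softmax_probabilities(
        rng.normal(size=(segments.n_segments, 4,
                         segments.config.segment_length)) * 2).astype(
        np.float32))


class TestReassembly:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_snps = int(rng.integers(10, 80))
        L = int(rng.choice([8, 16]))
        ov = int(rng.choice([0, 2, 5]))
        m = random_matrix(rng, int(rng.integers(1, 4)), n_snps)
        segs = b.segment_matrix(m, b.SegmentationConfig(segment_length=L,
                                                        overlap=ov))
        preds = random_predictions(rng, segs)
        cls, prob, dhat = b.reassemble(preds, segs)
        cls2, prob2, dhat2 = brute_force_reassemble(preds.probs, segs)
        np.testing.assert_array_equal(cls, cls2)
        np.testing.assert_allclose(prob, prob2, atol=1e-6)
        np.testing.assert_allclose(dhat, dhat2, atol=1e-6)

    def test_higher_confidence_window_wins(self):
        m = make_matrix(np.ones((1, 6), dtype=np.uint8))
        segs = b.segment_matrix(m, b.SegmentationConfig(segment_length=4,
                                                        overlap=2))
        probs = np.full((2, 4, 4), 0.05, dtype=np.float32)
        # window A says class 2 with 0.9 at global SNP 2 (its offset 2)
        probs[0, :, 2] = [0.04, 0.9, 0.03, 0.03]
        # window B says class 4 with 0.6 at the same SNP (its offset 0)
        probs[1, :, 0] = [0.2, 0.1, 0.1, 0.6]
        cls, prob, _ = b.reassemble(PredictionTensor(probs), segs)
        assert cls[0, 2] == 2
        assert prob[0, 2] == pytest.approx(0.9)

    def test_tie_goes_to_earlier_window(self):
        m = make_matrix(np.ones((1, 6), dtype=np.uint8))
        segs = b.segment_matrix(m, b.SegmentationConfig(segment_length=4,
                                                        overlap=2))
        probs = np.full((2, 4, 4), 0.25, dtype=np.float32)
        probs[0, :, 2] = [0.7, 0.1, 0.1, 0.1]  # class 1, p=0.7
        probs[1, :, 0] = [0.1, 0.1, 0.7, 0.1]  # class 3, same p
        cls, _, _ = b.reassemble(PredictionTensor(probs), segs)
        assert cls[0, 2] == 1


class TestPredictSegments:
    def _setup(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 4, 50)
        segs = b.segment_matrix(m, b.SegmentationConfig(segment_length=16,
                                                        overlap=4))
        net = b.build_model(b.ModelConfig(segment_length=16, depth=3,
                                          base_channels=8, kernel_size=3),
                            seed=3)
        return segs, net

    def test_shapes_and_normalization(self):
        segs, net = self._setup()
        preds = b.predict_segments(net, segs, batch_size=5)
        assert preds.probs.shape[0] == segs.n_segments
        np.testing.assert_allclose(preds.probs.sum(axis=1), 1.0, atol=1e-5)

    def test_batching_invariance(self):
        segs, net = self._setup()
        p1 = b.predict_segments(net, segs, batch_size=3).probs
        p2 = b.predict_segments(net, segs, batch_size=1000).probs
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_segment_length_mismatch_errors(self):
        segs, _ = self._setup()
        net = b.build_model(b.ModelConfig(segment_length=32, depth=3,
                                          base_channels=8, kernel_size=3))
        with pytest.raises(ValueError, match="segment"):
            b.predict_segments(net, segs)


class TestImpute:
    def test_pass_through_and_completion(self):
        rng = np.random.default_rng(4)
        truth = random_matrix(rng, 5, 40)
        masked, mask = mask_matrix(truth, 0.2, rng)
        net = b.build_model(b.ModelConfig(segment_length=16, depth=3,
                                          base_channels=8, kernel_size=3),
                            seed=4)
        res = b.impute(masked, net, b.SegmentationConfig(segment_length=16,
                                                         overlap=4))
        # observed sites unchanged, exact dosages, confidence 1
        np.testing.assert_array_equal(res.codes[~mask], truth.codes[~mask])
        np.testing.assert_array_equal(res.dosage[~mask],
                                      dosage_of_codes(truth.codes[~mask]))
        assert np.all(res.confidence[~mask] == 1.0)
        # masked sites completed with classes in {1..4}
        assert np.all((res.codes[mask] >= 1) & (res.codes[mask] <= 4))
        assert res.dosage.min() >= 0.0 and res.dosage.max() <= 2.0

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(5)
        truth = random_matrix(rng, 3, 30)
        net = b.build_model(b.ModelConfig(segment_length=16, depth=3,
                                          base_channels=8, kernel_size=3))
        res = b.impute(truth, net, b.SegmentationConfig(segment_length=16,
                                                        overlap=4))
        np.testing.assert_array_equal(res.codes, truth.codes)


class TestMafBins:
    def test_default_edges(self):
        bins = b.MafBinSpec()
        assert bins.edges[0] == 0.001 and bins.edges[-1] == 0.5
        assert bins.n_bins == 8

    def test_assignment_right_closed(self):
        bins = b.MafBinSpec()
        idx = bins.assign(np.array([0.0005, 0.001, 0.005, 0.0051, 0.5, 0.35]))
        assert idx.tolist() == [0, 0, 0, 1, 7, 6]

    def test_invalid_edges(self):
        with pytest.raises(ValueError):
            b.MafBinSpec(edges=(0.01, 0.005, 0.5))
        with pytest.raises(ValueError):
            b.MafBinSpec(edges=(0.001, 0.4))


class TestMetrics:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(6)
        true_c = rng.integers(1, 5, size=500)
        maf = rng.uniform(0.002, 0.5, size=500)
        rpt = b.binned_metrics(true_c, true_c, dosage_of_codes(true_c),
                               maf, b.MafBinSpec())
        for m in ("accuracy", "precision", "recall", "f1", "r2"):
            assert rpt.overall[m] == pytest.approx(1.0)
        for row in rpt.per_bin:
            if row["n_calls"]:
                assert row["accuracy"] == pytest.approx(1.0)

    def test_hand_worked_dosage_example(self):
        # dosages truth [0,1,2,1,0] vs prediction [0,1,2,0,0]:
        # accuracy 4/5; Pearson r = 2.6 / sqrt(2.8 * 3.2), r^2 = 0.754464
        true_c = np.array([1, 2, 4, 3, 1])
        pred_c = np.array([1, 2, 4, 1, 1])
        pred_d = dosage_of_codes(pred_c).astype(float)
        rpt = b.binned_metrics(true_c, pred_c, pred_d,
                               np.full(5, 0.3), b.MafBinSpec())
        assert rpt.overall["accuracy"] == pytest.approx(0.8)
        assert rpt.overall["r2"] == pytest.approx(2.6 ** 2 / (2.8 * 3.2),
                                                  rel=1e-9)

    def test_phase_swap_decouples_accuracy_from_r2(self):
        rng = np.random.default_rng(7)
        true_c = rng.choice([2, 3], size=400)
        swapped = np.where(true_c == 2, 3, 2).astype(true_c.dtype)
        # add a few non-het calls so dosage is not constant
        true_c = np.concatenate([true_c, [1, 4, 1, 4]])
        swapped = np.concatenate([swapped, [1, 4, 1, 4]])
        rpt = b.binned_metrics(true_c, swapped,
                               dosage_of_codes(swapped).astype(float),
                               np.full(true_c.size, 0.25), b.MafBinSpec())
        assert rpt.overall["accuracy"] == pytest.approx(4 / true_c.size)
        assert rpt.overall["r2"] == pytest.approx(1.0)

    def test_constant_dosage_r2_undefined(self):
        true_c = np.ones(10, dtype=int)
        rpt = b.binned_metrics(true_c, true_c, np.zeros(10),
                               np.full(10, 0.2), b.MafBinSpec())
        assert np.isnan(rpt.overall["r2"])

    def test_confusion_row_sums_are_true_counts(self):
        rng = np.random.default_rng(8)
        true_c = rng.integers(1, 5, size=300)
        pred_c = rng.integers(1, 5, size=300)
        rpt = b.binned_metrics(true_c, pred_c, dosage_of_codes(pred_c) * 1.0,
                               rng.uniform(0.01, 0.5, 300), b.MafBinSpec())
        np.testing.assert_array_equal(
            rpt.confusion.sum(axis=1),
            [np.sum(true_c == c) for c in (1, 2, 3, 4)])
        assert rpt.confusion.sum() == 300

    def test_absent_class_excluded_from_macro_average(self):
        true_c = np.array([1, 1, 4, 4])
        pred_c = np.array([1, 1, 4, 4])  # classes 2, 3 absent everywhere
        rpt = b.binned_metrics(true_c, pred_c, dosage_of_codes(pred_c) * 1.0,
                               np.full(4, 0.3), b.MafBinSpec())
        assert rpt.overall["precision"] == 1.0  # not dragged down by absents


class TestEvaluate:
    @staticmethod
    def _oracle_imputer(truth):
        def imputer(matrix):
            codes = np.where(matrix.codes == MISSING, truth.codes,
                             matrix.codes).astype(np.uint8)
            return ImputationResult(
                codes=codes, dosage=dosage_of_codes(codes).astype(np.float32),
                confidence=np.ones_like(codes, dtype=np.float32))
        return imputer

    def test_oracle_scores_one_everywhere(self):
        rng = np.random.default_rng(9)
        truth = random_matrix(rng, 20, 60)
        report = b.evaluate(truth, self._oracle_imputer(truth),
                            levels=(0.15,), replicates=2, seed=1)
        mean = report[0.15]["mean"]
        assert mean["overall"]["accuracy"] == pytest.approx(1.0)
        assert mean["overall"]["f1"] == pytest.approx(1.0)
        for row in mean["per_bin"]:
            if row["n_calls"]:
                assert row["accuracy"] == pytest.approx(1.0)

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(10)
        truth = random_matrix(rng, 10, 40)
        imp = self._oracle_imputer(truth)
        r1 = b.evaluate(truth, imp, levels=(0.05,), replicates=1, seed=3)
        r2 = b.evaluate(truth, imp, levels=(0.05,), replicates=1, seed=3)
        pd.testing.assert_frame_equal(b.inference_eval.report_frame(r1),
                                      b.inference_eval.report_frame(r2))

    def test_rejects_incomplete_truth(self):
        m = make_matrix(np.array([[1, 0, 2]], dtype=np.uint8))
        with pytest.raises(ValueError):
            b.evaluate(m, lambda x: None)

    def test_masked_fraction_is_exact(self):
        rng = np.random.default_rng(11)
        truth = random_matrix(rng, 6, 100)
        _, mask = mask_matrix(truth, 0.15, rng)
        assert np.all(mask.sum(axis=1) == 15)

    def test_report_frame_tidy(self):
        rng = np.random.default_rng(12)
        truth = random_matrix(rng, 10, 40)
        report = b.evaluate(truth, self._oracle_imputer(truth),
                            levels=(0.05, 0.25), replicates=2, seed=4)
        frame = b.inference_eval.report_frame(report)
        assert set(frame.columns) == {"level", "replicate", "bin", "metric",
                                      "value", "n_snps", "n_calls"}
        assert set(frame["level"]) == {0.05, 0.25}
        assert set(frame["replicate"]) == {1, 2}
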