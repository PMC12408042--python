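"""End-to-end imputation and the replicate-masked, MAF-binned evaluation.

Inference segments the (possibly incomplete) genotype matrix with the same
settings used in training, runs the network batch-wise, and reassembles
full-length predictions: where overlapping windows both cover a SNP, the
window whose winning class probability is highest supplies the call (ties go
to the earlier window). Only originally missing sites are replaced; observed
genotypes pass through unchanged.

Evaluation follows the replicate-masking protocol: the complete test matrix
is masked at fixed levels (default 5/15/25%, three replicates each), imputed,
and compared at the masked sites only. Metrics (accuracy, dosage R-squared,
macro precision/recall/F1) are computed per MAF bin by concatenating all
masked calls in the bin rather than averaging per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, GenotypeMatrix, compute_maf_matrix,
                          dosage_of_codes)
from .loss import expected_dosage, softmax_probabilities
from .model import UNet1D
from .segmentation import (SegmentationConfig, SegmentSet, _window_starts,
                           segment_matrix)
from .training import one_hot_segments

DEFAULT_BIN_EDGES = (0.001, 0.005, 0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass
class PredictionTensor:
    probs: np.ndarray  # [n_segments, 4, segment_length]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 3 or self.probs.shape[1] != 4:
            raise ValueError("probs must be [n_segments, 4, segment_length]")


@dataclass
class ImputationResult:
    codes: np.ndarray       # completed matrix, values in {1..4}
    dosage: np.ndarray      # expected alt dosage per site, in [0, 2]
    confidence: np.ndarray  # winning class probability per site


@dataclass(frozen=True)
class MafBinSpec:
    """Right-closed MAF bins; default (0.1%,0.5%], (0.5%,1%], ... (40%,50%]."""

    edges: tuple = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if e[-1] != 0.5:
            raise ValueError("last bin edge must be 0.5")
        object.__setattr__(self, "edges", e)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list[str]:
        return [f"({100 * a:g}%,{100 * b:g}%]"
                for a, b in zip(self.edges, self.edges[1:])]

    def assign(self, maf: np.ndarray) -> np.ndarray:
        """Bin index per SNP; MAF at or below the lowest edge joins bin 0."""
        idx = np.searchsorted(np.asarray(self.edges[1:]), np.asarray(maf),
                              side="left")
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class MetricsReport:
    overall: dict
    per_bin: list[dict]
    confusion: np.ndarray  # 4x4, rows = true class code 1..4
    n_calls: int


def predict_segments(model: UNet1D, segments: SegmentSet,
                     batch_size: int = 256) -> PredictionTensor:
    """Batched forward pass + softmax over every segment."""
    if segments.config.segment_length != model.config.segment_length:
        raise ValueError(
            f"segment store L={segments.config.segment_length} does not match "
            f"the model's segment_length {model.config.segment_length}")
    out = np.empty((segments.n_segments, 4, segments.config.segment_length),
                   dtype=np.float32)
    for lo in range(0, segments.n_segments, batch_size):
        hi = min(lo + batch_size, segments.n_segments)
        x = one_hot_segments(segments.codes[lo:hi],
                             segments.positions_norm[lo:hi])
        out[lo:hi] = softmax_probabilities(model.forward(x), axis=1)
    return PredictionTensor(probs=out)


def reassemble(predictions: PredictionTensor, segments: SegmentSet
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve overlapping windows to per-site (class, probability, dosage).

    Among the windows covering a SNP, the one whose maximum class probability
    at that position is highest wins; exact ties go to the earlier window.
    Returns arrays of shape [n_samples, n_snps]: class codes in {1..4},
    winning probability, and the winning window's expected dosage.
    """
    cfg = segments.config
    n_snps = segments.n_snps_original
    n_samples = segments.n_samples
    n_win = segments.segments_per_sample
    if predictions.probs.shape[0] != segments.n_segments \
            or segments.n_segments != n_samples * n_win:
        raise ValueError("predictions are not aligned to a complete segment set")
    L = cfg.segment_length
    probs = predictions.probs.reshape(n_samples, n_win, 4, L)
    starts = _window_starts(n_snps, cfg)

    best_prob = np.full((n_samples, n_snps), -1.0, dtype=np.float32)
    best_class = np.zeros((n_samples, n_snps), dtype=np.uint8)
    best_dosage = np.zeros((n_samples, n_snps), dtype=np.float32)
    for w, start in enumerate(starts):
        end = min(start + L, n_snps)
        width = end - start
        pw = probs[:, w, :, :width].astype(np.float64)
        maxp = pw.max(axis=1).astype(np.float32)
        cls = (pw.argmax(axis=1) + 1).astype(np.uint8)
        dhat = expected_dosage(pw).astype(np.float32)
        upd = maxp > best_prob[:, start:end]
        best_prob[:, start:end] = np.where(upd, maxp, best_prob[:, start:end])
        best_class[:, start:end] = np.where(upd, cls, best_class[:, start:end])
        best_dosage[:, start:end] = np.where(upd, dhat,
                                             best_dosage[:, start:end])
    if np.any(best_prob < 0):
        raise AssertionError("coverage violation: SNP not covered by any window")
    return best_class, best_prob, best_dosage


def impute(matrix: GenotypeMatrix, model: UNet1D,
           seg_config: SegmentationConfig, batch_size: int = 256
           ) -> ImputationResult:
    """Fill the MISSING sites of a matrix with the model's predictions.

    Observed genotypes pass through unchanged (dosage = exact integer count,
    confidence = 1).
    """
    segments = segment_matrix(matrix, seg_config)
    preds = predict_segments(model, segments, batch_size=batch_size)
    cls, prob, dhat = reassemble(preds, segments)
    missing = matrix.codes == MISSING
    codes = np.where(missing, cls, matrix.codes).astype(np.uint8)
    dosage = np.where(missing, dhat, 0.0).astype(np.float32)
    if np.any(~missing):
        dosage[~missing] = dosage_of_codes(matrix.codes[~missing])
    confidence = np.where(missing, prob, 1.0).astype(np.float32)
    return ImputationResult(codes=codes, dosage=np.clip(dosage, 0.0, 2.0),
                            confidence=confidence)


def _metric_block(true_c: np.ndarray, pred_c: np.ndarray,
                  pred_d: np.ndarray) -> dict:
    from scipy.stats import pearsonr
    from sklearn.metrics import precision_recall_fscore_support

    out = {"n_calls": int(true_c.size)}
    if true_c.size == 0:
        return {**out, "accuracy": np.nan, "r2": np.nan, "precision": np.nan,
                "recall": np.nan, "f1": np.nan}
    out["accuracy"] = float(np.mean(true_c == pred_c))
    true_d = dosage_of_codes(true_c).astype(np.float64)
    if np.ptp(true_d) == 0 or np.ptp(pred_d) == 0:
        out["r2"] = np.nan  # constant vector: correlation undefined
    else:
        r = pearsonr(true_d, np.asarray(pred_d, dtype=np.float64)).statistic
        out["r2"] = float(r * r)
    labels = sorted(set(np.unique(true_c)) | set(np.unique(pred_c)))
    p, r, f1, _ = precision_recall_fscore_support(
        true_c, pred_c, labels=labels, average="macro", zero_division=0)
    out.update(precision=float(p), recall=float(r), f1=float(f1))
    return out


def binned_metrics(true_classes: np.ndarray, pred_classes: np.ndarray,
                   pred_dosages: np.ndarray, maf_per_call: np.ndarray,
                   bins: MafBinSpec = MafBinSpec()) -> MetricsReport:
    """Concatenated-SNP metrics per MAF bin plus overall.

    All vectors are aligned per masked genotype call; ``maf_per_call`` carries
    each call's SNP-level MAF (from the unmasked ground truth).
    """
    true_c = np.asarray(true_classes)
    pred_c = np.asarray(pred_classes)
    pred_d = np.asarray(pred_dosages, dtype=np.float64)
    maf = np.asarray(maf_per_call, dtype=np.float64)
    if not (true_c.shape == pred_c.shape == pred_d.shape == maf.shape):
        raise ValueError("metric inputs must be aligned 1-D vectors")

    overall = _metric_block(true_c, pred_c, pred_d)
    bin_idx = bins.assign(maf)
    per_bin = []
    for b, label in enumerate(bins.labels):
        sel = bin_idx == b
        block = _metric_block(true_c[sel], pred_c[sel], pred_d[sel])
        block.update(bin=label, maf_lo=bins.edges[b], maf_hi=bins.edges[b + 1],
                     n_snps=int(np.unique(maf[sel]).size))
        per_bin.append(block)

    confusion = np.zeros((4, 4), dtype=np.int64)
    np.add.at(confusion, (true_c - 1, pred_c - 1), 1)
    return MetricsReport(overall=overall, per_bin=per_bin,
                         confusion=confusion, n_calls=int(true_c.size))


def mask_matrix(truth: GenotypeMatrix, level: float,
                rng: np.random.Generator) -> tuple[GenotypeMatrix, np.ndarray]:
    """Hide exactly round(level * n_snps) sites per sample (without
    replacement); returns the masked matrix and the boolean mask."""
    n_samples, n_snps = truth.codes.shape
    n_mask = int(round(level * n_snps))
    mask = np.zeros((n_samples, n_snps), dtype=bool)
    for i in range(n_samples):
        mask[i, rng.choice(n_snps, size=n_mask, replace=False)] = True
    masked_codes = np.where(mask, MISSING, truth.codes).astype(np.uint8)
    masked = GenotypeMatrix(codes=masked_codes, variants=truth.variants,
                            sample_ids=truth.sample_ids)
    return masked, mask


def evaluate(truth: GenotypeMatrix, imputer, levels=(0.05, 0.15, 0.25),
             replicates: int = 3, bins: MafBinSpec = MafBinSpec(),
             seed: int = 0) -> dict:
    """Replicate-masked evaluation against a complete ground-truth matrix.

    ``imputer`` is any callable mapping a GenotypeMatrix with missing sites to
    an :class:`ImputationResult` (see :func:`make_model_imputer`). Returns
    ``{level: {"replicates": [MetricsReport, ...], "mean": MetricsReport-like
    dict of replicate-averaged metrics}}``.
    """
    if np.any(truth.codes == MISSING):
        raise ValueError("evaluation truth must have no missing genotypes")
    maf = compute_maf_matrix(truth.codes)
    report: dict = {}
    for level in levels:
        reps = []
        for rep in range(replicates):
            rng = np.random.default_rng(
                [int(seed), int(round(level * 1000)), rep + 1])
            masked, mask = mask_matrix(truth, level, rng)
            result = imputer(masked)
            sel = mask
            reps.append(binned_metrics(
                truth.codes[sel], result.codes[sel], result.dosage[sel],
                np.broadcast_to(maf, truth.codes.shape)[sel], bins))
        report[level] = {"replicates": reps,
                         "mean": _average_reports(reps, bins)}
    return report


def make_model_imputer(model: UNet1D, seg_config: SegmentationConfig,
                       batch_size: int = 256):
    return lambda matrix: impute(matrix, model, seg_config,
                                 batch_size=batch_size)


_METRICS = ("accuracy", "r2", "precision", "recall", "f1")


def _average_reports(reps: list[MetricsReport], bins: MafBinSpec) -> dict:
    mean = {"overall": {m: float(np.nanmean([r.overall[m] for r in reps]))
                        for m in _METRICS}}
    mean["overall"]["n_calls"] = int(np.mean([r.n_calls for r in reps]))
    per_bin = []
    for b, label in enumerate(bins.labels):
        row = {"bin": label}
        for m in _METRICS:
            vals = [r.per_bin[b][m] for r in reps]
            row[m] = float(np.nanmean(vals)) if not all(
                np.isnan(v) for v in vals) else np.nan
        row["n_calls"] = int(np.mean([r.per_bin[b]["n_calls"] for r in reps]))
        row["n_snps"] = int(np.mean([r.per_bin[b]["n_snps"] for r in reps]))
        per_bin.append(row)
    mean["per_bin"] = per_bin
    return mean


def report_frame(report: dict, bins: MafBinSpec = MafBinSpec()) -> pd.DataFrame:
    """Tidy (level, replicate, bin, metric, value, n_snps, n_calls) table."""
    rows = []
    for level, block in report.items():
        for rep, rpt in enumerate(block["replicates"], start=1):
            for m in _METRICS:
                rows.append({"level": level, "replicate": rep, "bin": "overall",
                             "metric": m, "value": rpt.overall[m],
                             "n_snps": np.nan, "n_calls": rpt.n_calls})
            for row in rpt.per_bin:
                for m in _METRICS:
                    rows.append({"level": level, "replicate": rep,
                                 "bin": row["bin"], "metric": m,
                                 "value": row[m], "n_snps": row["n_snps"],
                                 "n_calls": row["n_calls"]})
    return pd.DataFrame(rows)
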