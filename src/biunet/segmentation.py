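"""Overlapping fixed-length segmentation of a genotype matrix.

A sample's encoded sequence of ``n_snps`` codes is cut into windows of
``segment_length`` SNPs advancing by ``stride = segment_length - overlap``;
the final window is padded at the tail with the PAD code (5). Each segment
carries a second channel of min-max normalized genomic positions computed
over the whole loaded SNP set, so that structurally similar windows from
different genomic regions remain distinguishable to the model.

Segments are persisted in HDF5 with support for contiguous batch reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .genotype_io import PAD, GenotypeMatrix


@dataclass(frozen=True)
class SegmentationConfig:
    segment_length: int = 128
    overlap: int = 16
    chunk_size: int = 256  # samples per processing chunk (memory knob)

    def __post_init__(self) -> None:
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")
        if not (0 <= self.overlap < self.segment_length):
            raise ValueError("overlap must satisfy 0 <= overlap < segment_length")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")

    @property
    def stride(self) -> int:
        return self.segment_length - self.overlap


@dataclass
class SegmentSet:
    """Flat store of segments, sample-major (all windows of sample 0 first)."""

    codes: np.ndarray           # [n_segments_total, L] uint8, values {0..5}
    positions_norm: np.ndarray  # [n_segments_total, L] float32 in [0, 1]
    sample_index: np.ndarray    # [n_segments_total] int32
    segment_index: np.ndarray   # [n_segments_total] int32, window ordinal
    config: SegmentationConfig
    n_snps_original: int
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.sample_index.max()) + 1 if self.n_segments else 0

    @property
    def segments_per_sample(self) -> int:
        return count_segments(self.n_snps_original,
                              self.config.segment_length, self.config.overlap)


def count_segments(n_snps: int, segment_length: int, overlap: int) -> int:
    """Number of windows per sample for the padded fixed-stride scheme."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not (0 <= overlap < segment_length):
        raise ValueError("overlap must satisfy 0 <= overlap < segment_length")
    if n_snps <= segment_length:
        return 1
    stride = segment_length - overlap
    return int(np.ceil((n_snps - overlap) / stride))


def normalize_positions(pos: np.ndarray) -> np.ndarray:
    """Min-max normalize genomic coordinates of the loaded SNP set to [0, 1]."""
    import warnings

    pos = np.asarray(pos, dtype=np.float64)
    if pos.ndim != 1 or pos.size == 0:
        raise ValueError("pos must be a non-empty 1-D array")
    if pos.size > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("positions must be strictly increasing")
    span = pos[-1] - pos[0]
    if span == 0:
        warnings.warn("single SNP (or zero span): positional channel is all zeros")
        return np.zeros_like(pos, dtype=np.float32)
    return ((pos - pos[0]) / span).astype(np.float32)


def _window_starts(n_snps: int, config: SegmentationConfig) -> np.ndarray:
    n_win = count_segments(n_snps, config.segment_length, config.overlap)
    return config.stride * np.arange(n_win, dtype=np.int64)


def segment_matrix(matrix: GenotypeMatrix,
                   config: SegmentationConfig) -> SegmentSet:
    """Cut every sample into overlapping windows with tail padding.

    Padded slots get code PAD=5 in the code channel and repeat the last real
    SNP's normalized coordinate in the position channel.
    """
    n_samples, n_snps = matrix.codes.shape
    L = config.segment_length
    starts = _window_starts(n_snps, config)
    n_win = len(starts)

    idx = starts[:, None] + np.arange(L)[None, :]        # [n_win, L]
    pad_mask = idx >= n_snps
    idx_c = np.minimum(idx, n_snps - 1)

    pnorm = normalize_positions(matrix.positions)
    pos_seg = np.broadcast_to(pnorm[idx_c], (n_win, L))

    all_codes = np.empty((n_samples * n_win, L), dtype=np.uint8)
    for lo in range(0, n_samples, config.chunk_size):
        hi = min(lo + config.chunk_size, n_samples)
        chunk = matrix.codes[lo:hi][:, idx_c]            # [chunk, n_win, L]
        chunk[:, pad_mask] = PAD
        all_codes[lo * n_win:hi * n_win] = chunk.reshape(-1, L)

    return SegmentSet(
        codes=all_codes,
        positions_norm=np.tile(pos_seg.astype(np.float32), (n_samples, 1)),
        sample_index=np.repeat(np.arange(n_samples, dtype=np.int32), n_win),
        segment_index=np.tile(np.arange(n_win, dtype=np.int32), n_samples),
        config=config,
        n_snps_original=n_snps,
        sample_ids=list(matrix.sample_ids),
    )


def desegment_codes(segments: SegmentSet) -> np.ndarray:
    """Exact code-level inverse of :func:`segment_matrix`.

    Raises if two windows disagree at an overlap site; probability-level
    overlap resolution lives in the inference module.
    """
    cfg = segments.config
    n_snps = segments.n_snps_original
    n_samples = segments.n_samples
    n_win = segments.segments_per_sample
    if segments.n_segments != n_samples * n_win:
        raise ValueError("segment set is incomplete or not sample-major")
    L = cfg.segment_length
    out = np.full((n_samples, n_snps), 255, dtype=np.uint8)
    codes = segments.codes.reshape(n_samples, n_win, L)
    starts = _window_starts(n_snps, cfg)
    for w, start in enumerate(starts):
        end = min(start + L, n_snps)
        width = end - start
        seg = codes[:, w, :width]
        existing = out[:, start:end]
        filled = existing != 255
        if np.any(filled & (existing != seg)):
            raise ValueError(
                f"conflicting codes at overlap of window {w}; "
                "use probability-level reassembly for model output")
        out[:, start:end] = seg
    if np.any(out == 255):
        raise AssertionError("coverage violation: some SNPs never written")
    return out


_H5_FIELDS = ("codes", "positions_norm", "sample_index", "segment_index")


def write_segment_store(segments: SegmentSet, path: str,
                        shuffle_seed: int | None = None) -> None:
    """Persist segments to HDF5; a shuffle order is stored as an index array."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("codes", data=segments.codes, dtype="uint8")
        f.create_dataset("positions_norm", data=segments.positions_norm,
                         dtype="float32")
        f.create_dataset("sample_index", data=segments.sample_index, dtype="int32")
        f.create_dataset("segment_index", data=segments.segment_index,
                         dtype="int32")
        if shuffle_seed is not None:
            rng = np.random.default_rng(shuffle_seed)
            f.create_dataset(
                "shuffle_index",
                data=rng.permutation(segments.n_segments).astype(np.int64))
            f.attrs["shuffle_seed"] = int(shuffle_seed)
        f.attrs["segment_length"] = segments.config.segment_length
        f.attrs["overlap"] = segments.config.overlap
        f.attrs["n_snps"] = segments.n_snps_original
        f.attrs["n_samples"] = segments.n_samples
        f.attrs["sample_ids"] = json.dumps(segments.sample_ids)


def read_segment_store(path: str, start: int = 0, stop: int | None = None,
                       expect_config: SegmentationConfig | None = None
                       ) -> SegmentSet:
    """Read a contiguous batch [start, stop) of segments without full load.

    ``expect_config`` enforces that the store was built with the same
    segmentation settings (required at inference).
    """
    with h5py.File(str(path), "r") as f:
        for name in _H5_FIELDS:
            if name not in f:
                raise KeyError(f"segment store is missing dataset {name!r}")
        cfg = SegmentationConfig(segment_length=int(f.attrs["segment_length"]),
                                 overlap=int(f.attrs["overlap"]))
        if expect_config is not None and (
                cfg.segment_length != expect_config.segment_length
                or cfg.overlap != expect_config.overlap):
            raise ValueError(
                f"segment store was built with L={cfg.segment_length}, "
                f"overlap={cfg.overlap}; expected L={expect_config.segment_length},"
                f" overlap={expect_config.overlap}")
        sl = slice(start, stop)
        return SegmentSet(
            codes=f["codes"][sl],
            positions_norm=f["positions_norm"][sl],
            sample_index=f["sample_index"][sl],
            segment_index=f["segment_index"][sl],
            config=cfg,
            n_snps_original=int(f.attrs["n_snps"]),
            sample_ids=json.loads(f.attrs["sample_ids"]),
        )


def read_shuffle_index(path: str) -> np.ndarray | None:
    with h5py.File(str(path), "r") as f:
        if "shuffle_index" in f:
            return f["shuffle_index"][:]
    return None
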