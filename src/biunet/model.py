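"""1-D denoising U-Net over encoded genotype segments (NumPy implementation).

Input is channel-first ``[batch, 7, segment_length]``: channels 0-5 are the
one-of-6 expansion of the genotype codes (missing, the four phased classes,
padding) and channel 6 is the min-max normalized genomic position. Output is
``[batch, 4, segment_length]`` logits over the four phased-genotype classes.

The encoder stacks ``depth`` blocks of 1-D convolution -> ReLU, with
max-pooling (factor 2) and dropout between levels and feature channels
doubling per level; the decoder mirrors it with nearest-neighbour upsampling,
channel halving, and skip connections that concatenate the matching encoder
features. A final width-1 convolution projects to the class logits.

Forward and backward passes are written directly against NumPy (im2col
convolutions); :mod:`biunet.training` supplies the optimizer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genotype_io import N_CLASSES, VOCABULARY_SIZE


@dataclass(frozen=True)
class ModelConfig:
    segment_length: int = 128
    depth: int = 6
    base_channels: int = 32
    kernel_size: int = 5
    dropout_rate: float = 0.1
    in_channels: int = VOCABULARY_SIZE + 1  # 6 code channels + 1 positional
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding convolutions)")
        if self.segment_length % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"segment_length {self.segment_length} must be divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.in_channels != VOCABULARY_SIZE + 1:
            raise ValueError("in_channels is fixed to vocabulary_size + 1 = 7")
        if self.n_classes != N_CLASSES:
            raise ValueError("n_classes is fixed to the 4 phased-genotype classes")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Conv1d:
    """Same-padding stride-1 1-D convolution with cached im2col backward."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((c_out, c_in, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        B, C, L = x.shape
        pad = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad))) if pad else x
        win = sliding_window_view(xp, self.k, axis=2)  # [B, C, L, k]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            B * L, C * self.k)
        y = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        if cache:
            self._cols = cols
        return np.ascontiguousarray(
            y.reshape(B, L, -1).transpose(0, 2, 1)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Co, L = dy.shape
        k, pad = self.k, (self.k - 1) // 2
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L, Co)
        self.gb = dyf.sum(axis=0).astype(np.float32)
        self.gW = (dyf.T @ self._cols).reshape(self.W.shape).astype(np.float32)
        self._cols = None
        # full correlation of dy with the kernel flipped along k
        dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
        win = sliding_window_view(dyp, k, axis=2)  # [B, Co, L+k-1, k]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            B * (L + k - 1), Co * k)
        wflip = np.ascontiguousarray(
            self.W[:, :, ::-1].transpose(1, 0, 2)).reshape(self.W.shape[1], -1)
        dxp = (cols @ wflip.T).reshape(B, L + k - 1, -1).transpose(0, 2, 1)
        return np.ascontiguousarray(dxp[:, :, pad:pad + L]).astype(np.float32)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class _ReLU:
    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        B, C, L = x.shape
        xr = x.reshape(B, C, L // 2, 2)
        idx = xr.argmax(axis=3)
        if cache:
            self._idx, self._L = idx, L
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, Lh = dy.shape
        dxr = np.zeros((B, C, Lh, 2), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        return dxr.reshape(B, C, self._L)


class _Upsample2:
    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = dy.shape
        return dy.reshape(B, C, L // 2, 2).sum(axis=3)


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class UNet1D:
    """The denoising network; see module docstring for the architecture."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        k = config.kernel_size
        d = config.depth

        self.enc_conv = []
        self.enc_relu = []
        c_prev = config.in_channels
        for i in range(d):
            self.enc_conv.append(_Conv1d(c_prev, ch[i], k, rng))
            self.enc_relu.append(_ReLU())
            c_prev = ch[i]
        self.pool = [_MaxPool2() for _ in range(d - 1)]
        self.drop = [_Dropout(config.dropout_rate) for _ in range(d - 1)]

        self.up = [_Upsample2() for _ in range(d - 1)]
        self.up_conv, self.up_relu = [], []
        self.merge_conv, self.merge_relu = [], []
        for i in range(d - 2, -1, -1):  # decoder levels, deepest first
            self.up_conv.append(_Conv1d(ch[i + 1], ch[i], k, rng))
            self.up_relu.append(_ReLU())
            self.merge_conv.append(_Conv1d(2 * ch[i], ch[i], k, rng))
            self.merge_relu.append(_ReLU())
        self.out_conv = _Conv1d(ch[0], config.n_classes, 1, rng)
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))

    # ------------------------------------------------------------------ api

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected input [B, {self.config.in_channels}, L], got {x.shape}")
        if x.shape[2] != self.config.segment_length:
            raise ValueError(
                f"expected segment_length {self.config.segment_length}, "
                f"got {x.shape[2]}")
        d = self.config.depth
        h = x
        skips = []
        for i in range(d - 1):
            h = self.enc_relu[i].forward(self.enc_conv[i].forward(h, training),
                                         training)
            skips.append(h)
            h = self.pool[i].forward(h, training)
            h = self.drop[i].forward(h, training, self._dropout_rng)
        h = self.enc_relu[d - 1].forward(
            self.enc_conv[d - 1].forward(h, training), training)
        self._skip_ch = [s.shape[1] for s in skips]
        for j, i in enumerate(range(d - 2, -1, -1)):
            h = self.up[j].forward(h, training)
            h = self.up_relu[j].forward(self.up_conv[j].forward(h, training),
                                        training)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.merge_relu[j].forward(
                self.merge_conv[j].forward(h, training), training)
        return self.out_conv.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate; gradients land in each layer's ``gW``/``gb``."""
        d = self.config.depth
        dh = self.out_conv.backward(np.asarray(dlogits, dtype=np.float32))
        dskips = [None] * (d - 1)
        for j in range(d - 2, -1, -1):  # reverse of decoder order
            i = d - 2 - j               # encoder level fed by decoder step j
            dh = self.merge_conv[j].backward(self.merge_relu[j].backward(dh))
            c_skip = self._skip_ch[i]
            dskips[i] = dh[:, :c_skip]
            dh = dh[:, c_skip:]
            dh = self.up_conv[j].backward(self.up_relu[j].backward(dh))
            dh = self.up[j].backward(dh)
        dh = self.enc_conv[d - 1].backward(self.enc_relu[d - 1].backward(dh))
        for i in range(d - 2, -1, -1):
            dh = self.drop[i].backward(dh)
            dh = self.pool[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc_conv[i].backward(self.enc_relu[i].backward(dh))

    # ------------------------------------------------------- param plumbing

    def _convs(self) -> list[tuple[str, _Conv1d]]:
        named = []
        for i, c in enumerate(self.enc_conv):
            named.append((f"enc{i}", c))
        for j, c in enumerate(self.up_conv):
            named.append((f"up{j}", c))
        for j, c in enumerate(self.merge_conv):
            named.append((f"merge{j}", c))
        named.append(("out", self.out_conv))
        return named

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for name, c in self._convs():
            out[f"{name}.W"] = c.W
            out[f"{name}.b"] = c.b
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for name, c in self._convs():
            out[f"{name}.W"] = c.gW
            out[f"{name}.b"] = c.gb
        return out

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for name, c in self._convs():
            c.W = params[f"{name}.W"].astype(np.float32).reshape(c.W.shape)
            c.b = params[f"{name}.b"].astype(np.float32).reshape(c.b.shape)


def build_model(config: ModelConfig, seed: int = 0) -> UNet1D:
    """Construct a seeded network; two builds from one config have identical
    parameter counts (and identical initial weights for the same seed)."""
    return UNet1D(config, seed=seed)


def count_parameters(model: UNet1D) -> int:
    return sum(p.size for p in model.parameters().values())


def save_checkpoint(model: UNet1D, path: str, metadata: dict | None = None
                    ) -> None:
    """Serialize parameters plus the config (and its hash) and run metadata."""
    payload = {f"param::{k}": v for k, v in model.parameters().items()}
    payload["__config__"] = np.array(json.dumps(asdict(model.config)))
    payload["__config_hash__"] = np.array(model.config.hash())
    payload["__meta__"] = np.array(json.dumps(metadata or {}))
    np.savez(str(path), **payload)


def load_checkpoint(path: str, expect_config: ModelConfig | None = None
                    ) -> tuple[UNet1D, dict]:
    with np.load(str(path), allow_pickle=False) as f:
        config = ModelConfig(**json.loads(str(f["__config__"])))
        stored_hash = str(f["__config_hash__"])
        if expect_config is not None and expect_config.hash() != stored_hash:
            raise ValueError(
                "checkpoint was trained with a different model configuration")
        meta = json.loads(str(f["__meta__"]))
        model = UNet1D(config, seed=0)
        model.set_parameters(
            {k[len("param::"):]: f[k] for k in f.files if k.startswith("param::")})
    return model, meta
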