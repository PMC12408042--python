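"""Curriculum-masked denoising training loop.

Each batch gets a fresh random mask: a fraction of the eligible positions
(non-padding genotypes with known truth) is set to the MISSING code in the
input copy while the truth is kept as the reconstruction target. The masking
rate follows a curriculum, rising linearly from 5% at the first epoch to 25%
at the last, so the model first learns from nearly complete haplotypes and is
then pushed toward robustness at high missingness. Validation is scored at
the fixed final rate on held-out samples so epochs are comparable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import HOM_ALT, HOM_REF, MISSING, VOCABULARY_SIZE
from .loss import LossConfig, hybrid_loss_and_grad
from .model import UNet1D
from .segmentation import SegmentSet


@dataclass(frozen=True)
class MaskingSpec:
    rate: float
    seed: int | None = None
    mode: str = "per-batch-dynamic"  # or "fixed-evaluation"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("masking rate must be in [0, 1]")


@dataclass
class TrainingConfig:
    epochs: int = 15
    batch_size: int = 64
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    start_rate: float = 0.05
    end_rate: float = 0.25
    schedule: str = "linear"  # or "step"
    val_fraction: float = 0.1
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_rate <= self.end_rate <= 1.0):
            raise ValueError("need 0 <= start_rate <= end_rate <= 1")
        if self.schedule not in ("linear", "step"):
            raise ValueError("schedule must be 'linear' or 'step'")


def eligible_positions(batch_codes: np.ndarray) -> np.ndarray:
    """Positions that may be masked / scored: non-PAD with a known class."""
    codes = np.asarray(batch_codes)
    return (codes >= HOM_REF) & (codes <= HOM_ALT)


def apply_random_mask(batch_codes: np.ndarray, spec: MaskingSpec,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mask exactly ``round(rate * n_eligible)`` positions to MISSING.

    Returns ``(masked_codes, mask_indicator, truth_labels)``; the truth array
    is an untouched copy of the input. Padding is never masked.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    codes = np.asarray(batch_codes)
    truth = codes.copy()
    eligible = eligible_positions(codes)
    flat_idx = np.flatnonzero(eligible)
    n_mask = int(round(spec.rate * flat_idx.size))
    chosen = rng.choice(flat_idx, size=n_mask, replace=False)
    masked = codes.copy()
    mask = np.zeros(codes.shape, dtype=bool)
    if n_mask:
        np.put(masked, chosen, MISSING)
        np.put(mask, chosen, True)
    return masked, mask, truth


def curriculum_rate(epoch: int, config: TrainingConfig) -> float:
    """Masking rate at a given epoch: start_rate at 0, end_rate at the last."""
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.epochs == 1:
        return config.end_rate
    t = epoch / (config.epochs - 1)
    if config.schedule == "step":
        t = round(t * 4) / 4  # quarter-steps, still hits both endpoints
    return config.start_rate + t * (config.end_rate - config.start_rate)


def one_hot_segments(codes: np.ndarray, positions_norm: np.ndarray
                     ) -> np.ndarray:
    """Stack one-of-6 code channels with the positional channel: [B, 7, L]."""
    codes = np.asarray(codes)
    B, L = codes.shape
    x = np.zeros((B, VOCABULARY_SIZE + 1, L), dtype=np.float32)
    b_idx = np.repeat(np.arange(B), L)
    l_idx = np.tile(np.arange(L), B)
    x[b_idx, codes.ravel(), l_idx] = 1.0
    x[:, VOCABULARY_SIZE, :] = positions_norm
    return x


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2)
                                                + self.eps)


def _batch_loss_and_step(model: UNet1D, codes: np.ndarray,
                         positions: np.ndarray, rate: float,
                         loss_cfg: LossConfig, rng: np.random.Generator,
                         opt: Adam | None) -> float:
    masked, mask, truth = apply_random_mask(
        codes, MaskingSpec(rate=rate), rng=rng)
    x = one_hot_segments(masked, positions)
    eligible = eligible_positions(truth)
    score_mask = mask & eligible if loss_cfg.masked_only else eligible
    logits = model.forward(x, training=opt is not None)
    loss, dlogits = hybrid_loss_and_grad(truth, logits, loss_cfg, score_mask)
    if opt is not None:
        model.backward(dlogits.astype(np.float32))
        opt.step(model.parameters(), model.gradients())
    return loss


def train(model: UNet1D, segments: SegmentSet, config: TrainingConfig,
          callback=None) -> tuple[UNet1D, list[dict]]:
    """Train the denoiser on a segment set.

    Samples (not segments) are split into train/validation to avoid leakage
    between overlapping windows of the same individual. The checkpointed
    state with the best validation loss is restored before returning.
    """
    rng = np.random.default_rng(config.seed)
    samples = np.unique(segments.sample_index)
    perm = rng.permutation(samples)
    n_val = max(1, int(round(config.val_fraction * len(samples)))) \
        if config.val_fraction > 0 and len(samples) > 1 else 0
    val_samples = set(perm[:n_val].tolist())
    is_val = np.isin(segments.sample_index, list(val_samples)) if n_val \
        else np.zeros(segments.n_segments, dtype=bool)
    train_idx = np.flatnonzero(~is_val)
    val_idx = np.flatnonzero(is_val)

    opt = Adam(model.parameters(), config.learning_rate,
               config.adam_beta1, config.adam_beta2, config.adam_eps)
    val_rng_seed = int(rng.integers(2 ** 31))
    history: list[dict] = []
    best_val = np.inf
    best_params = None

    for epoch in range(config.epochs):
        rate = curriculum_rate(epoch, config)
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo:lo + config.batch_size]
            loss = _batch_loss_and_step(
                model, segments.codes[sel], segments.positions_norm[sel],
                rate, config.loss, rng, opt)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            losses.append(loss)
        train_loss = float(np.mean(losses))

        if len(val_idx):
            vrng = np.random.default_rng(val_rng_seed)  # fixed mask per run
            vlosses = []
            for lo in range(0, len(val_idx), config.batch_size):
                sel = val_idx[lo:lo + config.batch_size]
                vlosses.append(_batch_loss_and_step(
                    model, segments.codes[sel], segments.positions_norm[sel],
                    config.end_rate, config.loss, vrng, None))
            val_loss = float(np.mean(vlosses))
        else:
            val_loss = train_loss

        history.append({"epoch": epoch, "rate": rate,
                        "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.parameters().items()}
        if callback is not None:
            callback(history[-1])

    if best_params is not None:
        model.set_parameters(best_params)
    return model, history
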