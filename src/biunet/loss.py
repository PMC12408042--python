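"""Hybrid training objective: penalized focal classification + dosage MSE.

The total loss over a batch of N eligible genotypes is

    L = (1 - lam) * L_class + lam * L_dosage

    L_class  = (1/N) sum_i P(y_i, yhat_i) * (1 - p_i)^gamma * (-log p_i)
    L_dosage = (1/N) sum_i (d_i - dhat_i)^2

where p_i is the softmax probability of the true class y_i, yhat_i is the
argmax class, P is a 4x4 penalty matrix with zero diagonal that charges
phase-switch errors (2 <-> 3: wrong phase, correct dosage) three times less
than dosage-changing errors, d_i is the true alternate-allele dosage
({1 -> 0, 2 -> 1, 3 -> 1, 4 -> 2}), and dhat_i = p(2) + p(3) + 2 p(4) is
the expected dosage under the predicted distribution.

Classes are coded 1..4 externally; arrays here use the 0..3 axis internally.
The penalty P(y, yhat) acts as a constant per-element weight (yhat is the
argmax, detached); gradients flow through the focal factor and the
cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default penalty scores: off-diagonal 3.0 except the phase-switch pair (1.0)
DEFAULT_PENALTY = np.array([
    [0.0, 3.0, 3.0, 3.0],
    [3.0, 0.0, 1.0, 3.0],
    [3.0, 1.0, 0.0, 3.0],
    [3.0, 3.0, 3.0, 0.0],
])

#: dosage of class axis index 0..3 (codes 1..4)
CLASS_DOSAGE = np.array([0.0, 1.0, 1.0, 2.0])


@dataclass(frozen=True)
class PenaltyMatrix:
    P: np.ndarray = field(default_factory=lambda: DEFAULT_PENALTY.copy())

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        if P.shape != (4, 4):
            raise ValueError("penalty matrix must be 4x4")
        if np.any(P < 0):
            raise ValueError("penalty scores must be non-negative")
        if np.any(np.diag(P) != 0):
            raise ValueError("penalty diagonal must be zero (correct predictions)")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class LossConfig:
    gamma: float = 2.0
    lam: float = 0.5
    penalty: PenaltyMatrix = field(default_factory=PenaltyMatrix)
    masked_only: bool = False  # restrict the loss to masked positions
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must be in [0, 1]")


def softmax_probabilities(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable (max-shifted) softmax along ``axis``."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check(labels: np.ndarray, probs: np.ndarray, mask: np.ndarray):
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if probs.shape[1] != 4:
        raise ValueError("probs must have 4 classes on axis 1")
    if labels.shape != mask.shape or labels.shape != (
            probs.shape[0],) + probs.shape[2:]:
        raise ValueError("labels/mask shape must match probs without class axis")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no eligible genotypes in batch")
    if np.any((labels[mask] < 1) | (labels[mask] > 4)):
        raise ValueError("eligible labels must be class codes in {1..4}")
    return labels, probs, mask, n


def classification_loss(true_labels: np.ndarray, probs: np.ndarray,
                        config: LossConfig, mask: np.ndarray) -> float:
    """Mean penalized focal cross-entropy over eligible elements."""
    labels, probs, mask, n = _check(true_labels, probs, mask)
    y0 = np.where(mask, labels - 1, 0)
    p_true = np.take_along_axis(probs, y0[:, None, ...], axis=1)[:, 0, ...]
    yhat = probs.argmax(axis=1)
    w = config.penalty.P[y0, yhat]
    p = np.clip(p_true, config.eps, 1.0)
    per_elem = w * (1.0 - p_true) ** config.gamma * (-np.log(p))
    return float(per_elem[mask].sum() / n)


def expected_dosage(probs: np.ndarray) -> np.ndarray:
    """dhat = p(het 0|1) + p(het 1|0) + 2 p(hom alt); class axis is axis 1."""
    probs = np.asarray(probs, dtype=np.float64)
    return np.tensordot(probs, CLASS_DOSAGE, axes=([1], [0]))


def dosage_loss(true_labels: np.ndarray, probs: np.ndarray,
                mask: np.ndarray) -> float:
    """Mean squared error of expected dosage against true dosage."""
    labels, probs, mask, n = _check(true_labels, probs, mask)
    y0 = np.where(mask, labels - 1, 0)
    d = CLASS_DOSAGE[y0]
    dhat = expected_dosage(probs)
    return float(((d - dhat) ** 2)[mask].sum() / n)


def hybrid_loss(true_labels: np.ndarray, probs: np.ndarray,
                config: LossConfig, mask: np.ndarray) -> float:
    """(1 - lam) * classification + lam * dosage."""
    cls = classification_loss(true_labels, probs, config, mask) \
        if config.lam < 1.0 else 0.0
    dos = dosage_loss(true_labels, probs, mask) if config.lam > 0.0 else 0.0
    return (1.0 - config.lam) * cls + config.lam * dos


def hybrid_loss_and_grad(true_labels: np.ndarray, logits: np.ndarray,
                         config: LossConfig, mask: np.ndarray
                         ) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient with respect to the logits.

    Used by the training loop; the gradient treats the penalty weight
    P(y, argmax) as a constant and differentiates the focal cross-entropy and
    the expected-dosage MSE through the softmax.
    """
    labels = np.asarray(true_labels)
    logits = np.asarray(logits, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    probs = softmax_probabilities(logits, axis=1)
    labels, probs_c, mask, n = _check(labels, probs, mask)

    y0 = np.where(mask, labels - 1, 0)
    p_true = np.take_along_axis(probs, y0[:, None, ...], axis=1)[:, 0, ...]
    p = np.clip(p_true, config.eps, 1.0)
    one_m_p = np.clip(1.0 - p_true, config.eps, 1.0)

    # classification term and d/dp_true
    yhat = probs.argmax(axis=1)
    w = config.penalty.P[y0, yhat]
    focal = one_m_p ** config.gamma
    ce = -np.log(p)
    cls_elem = w * focal * ce
    if config.gamma > 0:
        dfocal = -config.gamma * one_m_p ** (config.gamma - 1.0)
    else:
        dfocal = np.zeros_like(p)
    dcls_dp = w * (dfocal * ce - focal / p)

    # dosage term and gradient wrt logits
    d = CLASS_DOSAGE[y0]
    dhat = expected_dosage(probs)
    dos_elem = (d - dhat) ** 2

    m = mask.astype(np.float64)
    loss = ((1.0 - config.lam) * (cls_elem * m).sum()
            + config.lam * (dos_elem * m).sum()) / n

    # dL/dz_k: classification via dp_true/dz_k = p_true (delta_{k,y} - p_k)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, y0[:, None, ...], 1.0, axis=1)
    coef_c = (dcls_dp * p_true * m)[:, None, ...]
    grad_c = coef_c * (onehot - probs)
    # dosage: d dhat/dz_k = p_k (c_k - dhat)
    coef_d = (2.0 * (dhat - d) * m)[:, None, ...]
    cshape = (1, 4) + (1,) * (probs.ndim - 2)
    grad_d = coef_d * probs * (CLASS_DOSAGE.reshape(cshape) - dhat[:, None, ...])

    grad = ((1.0 - config.lam) * grad_c + config.lam * grad_d) / n
    return float(loss), grad
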