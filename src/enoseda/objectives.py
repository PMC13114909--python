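"""Loss functions and the adversarial-intensity schedule.

The three training stages combine: label-smoothed cross-entropy for
classification, a center loss pulling penultimate features toward learnable
per-class centers (with its own plain-SGD update rule), and per-branch
domain-adversarial binary cross-entropy evaluated through the gradient
reversal layer.  The reversal intensity ramps from 0 to its maximum along a
sigmoid-shaped epoch schedule so the adversarial signal cannot destabilise
early training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, concat, grl

# defaults as used by the staged protocol
LABEL_SMOOTHING = 0.05
CENTER_WEIGHT = 0.01  # lambda_c
DOMAIN_WEIGHT = 0.5  # lambda_d
CENTER_LR = 0.5
LAMBDA_LOCAL_MAX = 0.2
LAMBDA_GLOBAL_MAX = 0.1


@dataclass
class LossConfig:
    label_smoothing: float = LABEL_SMOOTHING
    center_weight: float = CENTER_WEIGHT
    domain_weight: float = DOMAIN_WEIGHT
    center_lr: float = CENTER_LR

    def __post_init__(self):
        if not (0 <= self.label_smoothing < 1):
            raise ValueError("label smoothing must be in [0, 1)")
        if self.center_weight < 0 or self.domain_weight < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class AdversarialConfig:
    lambda_local_max: float = LAMBDA_LOCAL_MAX
    lambda_global_max: float = LAMBDA_GLOBAL_MAX

    def lambdas_at(self, epoch: int, total_epochs: int) -> tuple[float, float]:
        return (lambda_schedule(epoch, total_epochs, self.lambda_local_max),
                lambda_schedule(epoch, total_epochs, self.lambda_global_max))


def smoothed_cross_entropy(logits: Tensor, y_true: np.ndarray, eps: float,
                           n_classes: int) -> Tensor:
    """Mean cross-entropy against labels smoothed to (1-eps) + eps/C."""
    if not (0 <= eps < 1):
        raise ValueError("eps must be in [0, 1)")
    y_true = np.asarray(y_true, dtype=np.int64)
    onehot = np.zeros((y_true.shape[0], n_classes))
    onehot[np.arange(y_true.shape[0]), y_true] = 1.0
    smoothed = (1.0 - eps) * onehot + eps / n_classes
    logp = logits.log_softmax(axis=-1)
    return -(logp * smoothed).sum(axis=-1).mean()


def center_loss(h: Tensor, y_true: np.ndarray, centers: np.ndarray) -> Tensor:
    """Mean squared distance from each penultimate feature to its class center.

    ``centers`` is treated as a constant here; the centers' own update is the
    dedicated SGD step in :func:`update_centers`.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    if y_true.size and (y_true.max() >= centers.shape[0] or y_true.min() < 0):
        raise ValueError("batch contains a label without a center row")
    diff = h - centers[y_true]
    return (diff**2).sum(axis=-1).mean()


def update_centers(h: np.ndarray, y_true: np.ndarray, centers: np.ndarray,
                   center_lr: float = CENTER_LR) -> np.ndarray:
    """One plain-SGD step on the unweighted center loss, w.r.t. centers only.

    d L_center / d c_k = -(2/N) sum_{i: y_i=k} (h_i - c_k); classes absent from
    the batch keep their center bit-identical.  With lr 0.5 and a single-sample
    batch the center lands exactly on h.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    h = np.asarray(h, dtype=np.float64)
    n = y_true.shape[0]
    new_centers = centers.copy()
    for k in np.unique(y_true):
        mask = y_true == k
        grad = -2.0 / n * (h[mask] - centers[k]).sum(axis=0)
        new_centers[k] = centers[k] - center_lr * grad
    return new_centers


def init_centers(n_classes: int, dim: int = 128) -> np.ndarray:
    return np.zeros((n_classes, dim))


def domain_adversarial_loss(source_features: Tensor, target_features: Tensor,
                            discriminator, lambda_g: float) -> Tensor:
    """Binary-cross-entropy domain loss through the gradient reversal layer.

    Source samples carry domain label 0 and target samples label 1.  The
    discriminator emits raw logits; the loss uses the numerically stable
    softplus form  BCE(z, y) = softplus(z) - y*z,  which equals
    -[y log D + (1-y) log(1-D)] for D = sigmoid(z).  Minimising it trains the
    discriminator, while the reversed gradient pushes the extractor to make
    the two domains indistinguishable.
    """
    if lambda_g < 0:
        raise ValueError("lambda must be >= 0")
    n_s, n_t = source_features.shape[0], target_features.shape[0]
    if n_s < 1 or n_t < 1:
        raise ValueError("both domains must contribute at least one sample")
    feats = concat([source_features, target_features], axis=0)
    logits = discriminator(grl(feats, lambda_g)).reshape(n_s + n_t)
    y = np.concatenate([np.zeros(n_s), np.ones(n_t)])
    return (logits.softplus() - logits * y).mean()


def lambda_schedule(e: int, E: int, lambda_max: float) -> float:
    """Sigmoid ramp lambda(e) = lambda_max * (2 / (1 + exp(-10 e / E)) - 1)."""
    if E < 1:
        raise ValueError("total epochs E must be >= 1")
    if not (0 <= e <= E):
        raise ValueError("epoch e must satisfy 0 <= e <= E")
    return lambda_max * (2.0 / (1.0 + math.exp(-10.0 * e / E)) - 1.0)


def stage1_loss(l_cls: Tensor | float, l_center: Tensor | float,
                lambda_c: float = CENTER_WEIGHT):
    """Pretraining/fine-tuning objective: L_cls + lambda_c * L_center."""
    return l_cls + lambda_c * l_center


def stage2_loss(l_cls_source: Tensor | float, l_dom_local: Tensor | float,
                l_dom_global: Tensor | float, lambda_d: float = DOMAIN_WEIGHT):
    """Alignment objective: L_cls^s + lambda_d (L_dom^local + L_dom^global)."""
    return l_cls_source + lambda_d * (l_dom_local + l_dom_global)
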