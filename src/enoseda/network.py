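"""The multi-granularity domain-adversarial network.

Architecture summary for a 10-channel x 120-step input (instance-normalised
per channel inside the forward pass):

* **CNN branch** (local temporal dynamics): three conv blocks
  (kernel 5 / 32 filters, kernel 5 / 64, kernel 3 / 128, each with batch norm,
  ReLU and max-pool 2, so the temporal axis shrinks 120 -> 60 -> 30 -> 15),
  adaptive average pooling to length 1, then FC 128 -> 128 + BN + ReLU.
* **Self-attention branch** (global context): transpose to time-major,
  linear 10 -> 64 + ReLU, sinusoidal positional encoding, two pre-layer-norm
  transformer encoder layers (4 heads, d_k = 16, feed-forward 256), temporal
  mean pooling, FC 64 -> 128 + BN + ReLU.
* **Adaptive fusion**: a scalar gate a = sigmoid(MLP([f_cnn; f_attn])) weights
  the branches, and [a*f_cnn; (1-a)*f_attn] is projected to the 256-d fused
  feature.  The gate's output layer starts at zero so training begins at
  a = 0.5.
* **Classifier head**: FC 256 -> 128 + BN + ReLU (the penultimate feature fed
  to the center loss), dropout 0.5, linear to class logits.
* **Domain discriminators**: one per branch, MLP 128 -> 128 -> 64 -> 1 with
  ReLU and dropout 0.3, fed through a gradient reversal layer.

Single-branch and concatenation-fusion ablation variants are built from the
same parts via constructor flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import N_SENSORS, N_TIMESTEPS, instance_normalize_array
from .nn import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    concat,
    grl,
)

FEATURE_DIM = 128  # d: each branch's output width
FUSED_DIM = 256  # d_f: fused feature width
D_MODEL = 64  # d_m: attention model width
N_HEADS = 4
N_ENCODER_LAYERS = 2


@dataclass
class FeatureBundle:
    """All tap points of one forward pass (batched Tensors)."""

    f_cnn: Tensor | None
    f_attn: Tensor | None
    alpha: Tensor | None  # (N, 1) scalar gate per sample
    f_fused: Tensor
    h: Tensor  # classifier penultimate feature, (N, 128)
    logits: Tensor


def positional_encoding(T: int, d_m: int) -> np.ndarray:
    """Sinusoidal position code: sin on even columns, cos on odd columns."""
    if d_m % 2:
        raise ValueError("model dimension must be even")
    pos = np.arange(T, dtype=np.float64)[:, None]
    i = np.arange(d_m // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_m)
    pe = np.zeros((T, d_m))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class CNNBranch(Module):
    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(N_SENSORS, 32, 5, 2, rng)
        self.bn1 = BatchNorm1d(32)
        self.conv2 = Conv1d(32, 64, 5, 2, rng)
        self.bn2 = BatchNorm1d(64)
        self.conv3 = Conv1d(64, 128, 3, 1, rng)
        self.bn3 = BatchNorm1d(128)
        self.fc = Linear(128, FEATURE_DIM, rng)
        self.bn_fc = BatchNorm1d(FEATURE_DIM)
        self.last_temporal_lengths: list[int] = []

    def forward(self, x: Tensor) -> Tensor:
        lengths = [x.shape[2]]
        for conv, bn in ((self.conv1, self.bn1), (self.conv2, self.bn2),
                         (self.conv3, self.bn3)):
            x = bn(conv(x)).relu().maxpool1d(2)
            lengths.append(x.shape[2])
        x = x.mean(axis=2)  # adaptive average pool to length 1
        lengths.append(1)
        self.last_temporal_lengths = lengths
        return self.bn_fc(self.fc(x)).relu()


class AttentionBranch(Module):
    def __init__(self, rng: np.random.Generator, dropout: float = 0.1):
        super().__init__()
        self.in_proj = Linear(N_SENSORS, D_MODEL, rng)
        self.pe = Tensor(positional_encoding(N_TIMESTEPS, D_MODEL))
        self.layers = [
            TransformerEncoderLayer(D_MODEL, N_HEADS, 4 * D_MODEL, dropout, rng)
            for _ in range(N_ENCODER_LAYERS)
        ]
        self.fc = Linear(D_MODEL, FEATURE_DIM, rng)
        self.bn_fc = BatchNorm1d(FEATURE_DIM)

    def forward(self, x: Tensor) -> Tensor:
        x = x.swapaxes(1, 2)  # (N, C, T) -> (N, T, C)
        x = self.in_proj(x).relu() + self.pe
        for layer in self.layers:
            x = layer(x)
        x = x.mean(axis=1)  # temporal mean pooling
        return self.bn_fc(self.fc(x)).relu()


class FusionGate(Module):
    """Scalar gate a = sigmoid(W2 ReLU(W1 [f_cnn; f_attn] + b1) + b2)."""

    def __init__(self, rng: np.random.Generator, hidden: int = 64):
        super().__init__()
        self.fc1 = Linear(2 * FEATURE_DIM, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng, zero_init=True)  # start at a = 0.5

    def forward(self, cat: Tensor) -> Tensor:
        return self.fc2(self.fc1(cat).relu()).sigmoid()


class ClassifierHead(Module):
    def __init__(self, in_dim: int, n_classes: int, rng: np.random.Generator,
                 dropout: float = 0.5):
        super().__init__()
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.fc1 = Linear(in_dim, 128, rng)
        self.bn = BatchNorm1d(128)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(128, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, f: Tensor) -> tuple[Tensor, Tensor]:
        h = self.bn(self.fc1(f)).relu()
        logits = self.fc2(self.drop(h))
        return h, logits


class Discriminator(Module):
    """Domain discriminator; outputs a raw logit (sigmoid lives in the loss)."""

    def __init__(self, rng: np.random.Generator, in_dim: int = FEATURE_DIM,
                 dropout: float = 0.3):
        super().__init__()
        self.fc1 = Linear(in_dim, 128, rng)
        self.drop1 = Dropout(dropout, rng)
        self.fc2 = Linear(128, 64, rng)
        self.drop2 = Dropout(dropout, rng)
        self.fc3 = Linear(64, 1, rng)

    def forward(self, f: Tensor) -> Tensor:
        if f.shape[-1] != self.fc1.weight.shape[0]:
            raise ValueError("discriminator input width mismatch")
        z = self.drop1(self.fc1(f).relu())
        z = self.drop2(self.fc2(z).relu())
        return self.fc3(z)


def grl_apply(f: Tensor, lam: float) -> Tensor:
    """Gradient reversal: forward identity; backward gradient scaled by -lam."""
    return grl(f, lam)


class MGDANet(Module):
    """Full dual-branch network; ablation variants via constructor flags.

    ``branches`` in {"both", "cnn", "attn"}; ``fusion`` in {"adaptive",
    "concat"} (only meaningful with both branches).  Single-branch variants
    bypass fusion and feed their 128-d feature straight to a matching head.
    """

    def __init__(self, n_classes: int, seed: int = 0, branches: str = "both",
                 fusion: str = "adaptive"):
        super().__init__()
        if branches not in ("both", "cnn", "attn"):
            raise ValueError(f"unknown branches setting {branches!r}")
        if fusion not in ("adaptive", "concat"):
            raise ValueError(f"unknown fusion setting {fusion!r}")
        self.branches = branches
        self.fusion = fusion
        self.arch_seed = seed
        rng = np.random.default_rng(seed)
        self.cnn = CNNBranch(rng) if branches in ("both", "cnn") else None
        self.attn = AttentionBranch(rng) if branches in ("both", "attn") else None
        if branches == "both":
            self.gate = FusionGate(rng) if fusion == "adaptive" else None
            self.fuse_proj = Linear(2 * FEATURE_DIM, FUSED_DIM, rng)
            self.fuse_bn = BatchNorm1d(FUSED_DIM)
            head_in = FUSED_DIM
        else:
            self.gate = None
            head_in = FEATURE_DIM
        self.head = ClassifierHead(head_in, n_classes, rng)
        self.disc_local = Discriminator(rng)
        self.disc_global = Discriminator(rng)
        self.n_classes = n_classes

    # -- forward --------------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor) -> FeatureBundle:
        if isinstance(x, Tensor):
            x = x.data
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (N_SENSORS, N_TIMESTEPS):
            raise ValueError(f"expected (n, {N_SENSORS}, {N_TIMESTEPS}) input, "
                             f"got {x.shape}")
        xt = Tensor(instance_normalize_array(x))
        f_cnn = self.cnn(xt) if self.cnn is not None else None
        f_attn = self.attn(xt) if self.attn is not None else None
        alpha = None
        if self.branches == "both":
            cat = concat([f_cnn, f_attn], axis=-1)
            if self.fusion == "adaptive":
                alpha = self.gate(cat)
                weighted = concat([alpha * f_cnn, (1.0 - alpha) * f_attn], axis=-1)
            else:
                weighted = cat
            f_fused = self.fuse_bn(self.fuse_proj(weighted)).relu()
        else:
            f_fused = f_cnn if f_cnn is not None else f_attn
        h, logits = self.head(f_fused)
        return FeatureBundle(f_cnn, f_attn, alpha, f_fused, h, logits)

    # -- parameter groups for the staged optimizers ---------------------------
    def extractor_parameters(self) -> list[Tensor]:
        params = []
        for mod in (self.cnn, self.attn):
            if mod is not None:
                params.extend(mod.parameters())
        params.extend(self.fusion_parameters())
        return params

    def branch_parameters(self) -> list[Tensor]:
        params = []
        for mod in (self.cnn, self.attn):
            if mod is not None:
                params.extend(mod.parameters())
        return params

    def fusion_parameters(self) -> list[Tensor]:
        if self.branches != "both":
            return []
        params = list(self.fuse_proj.parameters()) + list(self.fuse_bn.parameters())
        if self.gate is not None:
            params.extend(self.gate.parameters())
        return params

    def discriminator_parameters(self) -> list[Tensor]:
        return self.disc_local.parameters() + self.disc_global.parameters()

    def replace_head(self, n_classes: int, seed: int):
        """Swap in a fresh classifier head; all upstream parameters untouched."""
        head_in = FUSED_DIM if self.branches == "both" else FEATURE_DIM
        self.head = ClassifierHead(head_in, n_classes, np.random.default_rng(seed))
        self.head.train(self.training)
        self.n_classes = n_classes

    def architecture(self) -> dict:
        return {"n_classes": self.n_classes, "branches": self.branches,
                "fusion": self.fusion, "seed": self.arch_seed}


# ---------------------------------------------------------------------------
# checkpoints: weight blob + versioned JSON manifest
# ---------------------------------------------------------------------------

CHECKPOINT_FORMAT_VERSION = 1


def save_checkpoint(model: MGDANet, path: str | Path, stage: str, seed: int,
                    epoch: int, extra: dict | None = None):
    path = Path(path)
    manifest = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "architecture": model.architecture(),
        "stage": stage,
        "seed": seed,
        "epoch": epoch,
    }
    if extra:
        manifest.update(extra)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> tuple[MGDANet, dict]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    if manifest["format_version"] != CHECKPOINT_FORMAT_VERSION:
        raise ValueError("unsupported checkpoint format version")
    arch = manifest["architecture"]
    model = MGDANet(arch["n_classes"], seed=arch["seed"], branches=arch["branches"],
                    fusion=arch["fusion"])
    with np.load(path.with_suffix(".npz")) as blob:
        model.load_state_dict({k: blob[k] for k in blob.files})
    return model, manifest
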