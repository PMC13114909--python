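"""Three-stage transfer protocol, ablation variants, and label-efficiency runs.

Stage 1 pretrains the full network on the labeled source domain with
label-smoothed cross-entropy plus center loss (Adam 1e-3, cosine annealing,
best-validation checkpoint).  Stage 2 aligns source and target features by
adversarial training of per-branch domain discriminators through gradient
reversal (extractor Adam 2e-4, discriminators Adam 1e-3, sigmoid-ramped
reversal intensity; target labels are never read).  Stage 3 swaps in a fresh
classifier head for the target label space, reinitialises the class centers,
and fine-tunes end-to-end with differential learning rates (branches 3e-5,
fusion 5e-5, head 1e-4; best-validation checkpoint).

The ablation driver re-runs the pipeline with exactly one component removed
or simplified, and the label-efficiency driver holds Stages 1-2 fixed while
repeating Stage 3 on stratified subsamples of the labeled target training
set.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import objectives as obj
from .datamodel import (
    LabeledDataset,
    SplitSpec,
    Standardizer,
    apply_standardizer,
    day_wise_split,
    fit_standardizer,
    stratified_subsample,
    stratified_validation_split,
)
from .metrics import MetricsReport, compute_metrics
from .network import MGDANet
from .nn import Adam, CosineAnnealing, Tensor, no_grad

ABLATION_VARIANTS = (
    "cnn_only", "attn_only", "concat_fusion", "no_da",
    "local_only_da", "global_only_da", "no_finetune", "full",
)

DEFAULT_BATCH_SIZE = 32
STAGE1_LR = 1e-3
STAGE2_LR_EXTRACTOR = 2e-4
STAGE2_LR_DISCRIMINATOR = 1e-3
STAGE3_LR_BRANCHES = 3e-5
STAGE3_LR_FUSION = 5e-5
STAGE3_LR_HEAD = 1e-4
DEFAULT_EPOCHS = (200, 200, 300)


@dataclass
class StageSpec:
    stage: str  # pretrain | align | finetune
    epochs: int
    batch_size: int = DEFAULT_BATCH_SIZE
    checkpoint_rule: str = "best_val_accuracy"  # or last_epoch

    def __post_init__(self):
        if self.stage not in ("pretrain", "align", "finetune"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ExperimentResult:
    variant_name: str
    seeds: list[int]
    per_seed_metrics: list[MetricsReport]

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.per_seed_metrics])

    def mean_sd(self, name: str) -> tuple[float, float]:
        v = self.metric_values(name)
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def summary(self) -> dict:
        out = {"variant": self.variant_name, "seeds": self.seeds}
        for name in ("overall_accuracy", "f1_macro", "kappa",
                     "macro_precision", "macro_recall"):
            m, s = self.mean_sd(name)
            out[name] = {"mean": m, "sd": s}
        return out


def derive_seed(master: int, tag: str) -> int:
    """Stable sub-seed derivation: master seed + purpose tag -> int < 2^31."""
    digest = hashlib.blake2s(f"{master}:{tag}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def standardize_dataset(ds: LabeledDataset, s: Standardizer) -> np.ndarray:
    """Apply a fitted flat-feature standardizer; returns an (n, 10, 120) stack."""
    x = ds.to_array()
    flat = apply_standardizer(s, x.reshape(len(ds), -1))
    return flat.reshape(x.shape)


def fit_input_standardizer(ds: LabeledDataset, fitted_on: str) -> Standardizer:
    x = ds.to_array().reshape(len(ds), -1)
    return fit_standardizer(x, fitted_on)


def _predict(model: MGDANet, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    model.eval()
    preds = []
    with no_grad():
        for i in range(0, len(x), batch_size):
            preds.append(model(x[i : i + batch_size]).logits.data.argmax(axis=1))
    return np.concatenate(preds) if preds else np.zeros(0, dtype=np.int64)


def _accuracy(model: MGDANet, x: np.ndarray, y: np.ndarray) -> float:
    return float((_predict(model, x) == y).mean())


def evaluate(model: MGDANet, test: LabeledDataset,
             standardizer: Standardizer | None = None) -> MetricsReport:
    """Inference-mode evaluation producing the full metrics report."""
    if model.n_classes != test.n_classes:
        raise ValueError(
            f"model head has {model.n_classes} classes but test set has "
            f"{test.n_classes}")
    x = standardize_dataset(test, standardizer) if standardizer else test.to_array()
    y_pred = _predict(model, x)
    return compute_metrics(test.labels, y_pred, test.n_classes)


# ---------------------------------------------------------------------------
# stage 1: source pretraining
# ---------------------------------------------------------------------------

def pretrain_source(
    source: LabeledDataset,
    seed: int,
    epochs: int = DEFAULT_EPOCHS[0],
    batch_size: int = DEFAULT_BATCH_SIZE,
    lr: float = STAGE1_LR,
    val_fraction: float = 0.2,
    loss_cfg: obj.LossConfig | None = None,
    branches: str = "both",
    fusion: str = "adaptive",
    standardizer: Standardizer | None = None,
    log: list | None = None,
) -> tuple[MGDANet, dict]:
    """Train the full network on labeled source data; keep the best-val model."""
    loss_cfg = loss_cfg or obj.LossConfig()
    fit_ds, val_ds = stratified_validation_split(
        source, val_fraction, derive_seed(seed, "stage1/val_split"))
    x_fit = standardize_dataset(fit_ds, standardizer) if standardizer else fit_ds.to_array()
    x_val = standardize_dataset(val_ds, standardizer) if standardizer else val_ds.to_array()
    y_fit, y_val = fit_ds.labels, val_ds.labels

    model = MGDANet(source.n_classes, seed=derive_seed(seed, "stage1/init"),
                    branches=branches, fusion=fusion)
    centers = obj.init_centers(source.n_classes)
    params = model.branch_parameters() + model.fusion_parameters() + model.head.parameters()
    optimizer = Adam(params, lr)
    scheduler = CosineAnnealing([optimizer], epochs)
    rng = np.random.default_rng(derive_seed(seed, "stage1/batches"))

    best = {"val_accuracy": -1.0, "epoch": -1, "state": None, "centers": None}
    n = len(x_fit)
    for epoch in range(epochs):
        scheduler.set_epoch(epoch)
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            bundle = model(x_fit[idx])
            l_cls = obj.smoothed_cross_entropy(
                bundle.logits, y_fit[idx], loss_cfg.label_smoothing, source.n_classes)
            l_cen = obj.center_loss(bundle.h, y_fit[idx], centers)
            loss = obj.stage1_loss(l_cls, l_cen, loss_cfg.center_weight)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            centers = obj.update_centers(bundle.h.data, y_fit[idx], centers,
                                         loss_cfg.center_lr)
            epoch_loss += loss.item() * len(idx)
        val_acc = _accuracy(model, x_val, y_val)
        if log is not None:
            log.append({"stage": "pretrain", "epoch": epoch,
                        "loss": epoch_loss / n, "val_accuracy": val_acc})
        if val_acc > best["val_accuracy"]:
            best.update(val_accuracy=val_acc, epoch=epoch,
                        state=model.state_dict(), centers=centers.copy())
    model.load_state_dict(best["state"])
    info = {"stage": "pretrain", "seed": seed, "selection_epoch": best["epoch"],
            "val_accuracy": best["val_accuracy"], "centers": best["centers"],
            "fit_sample_ids": fit_ds.sample_ids, "val_sample_ids": val_ds.sample_ids}
    return model, info


# ---------------------------------------------------------------------------
# stage 2: multi-granularity adversarial alignment
# ---------------------------------------------------------------------------

def adversarial_align(
    model: MGDANet,
    source: LabeledDataset,
    target_train: LabeledDataset,
    seed: int,
    epochs: int = DEFAULT_EPOCHS[1],
    batch_size: int = DEFAULT_BATCH_SIZE,
    lr_extractor: float = STAGE2_LR_EXTRACTOR,
    lr_discriminator: float = STAGE2_LR_DISCRIMINATOR,
    loss_cfg: obj.LossConfig | None = None,
    adv_cfg: obj.AdversarialConfig | None = None,
    granularities: tuple[str, ...] = ("local", "global"),
    standardizer: Standardizer | None = None,
    log: list | None = None,
) -> tuple[MGDANet, dict]:
    """Align source/target features adversarially; target labels never read.

    Each step draws equal-size mini-batches from both domains (the smaller
    side cycles); returns the last-epoch model.
    """
    if len(target_train) == 0:
        raise ValueError("target training set is empty")
    loss_cfg = loss_cfg or obj.LossConfig()
    adv_cfg = adv_cfg or obj.AdversarialConfig()
    for g in granularities:
        if g not in ("local", "global"):
            raise ValueError(f"unknown granularity {g!r}")

    x_src = standardize_dataset(source, standardizer) if standardizer else source.to_array()
    y_src = source.labels
    x_tgt = (standardize_dataset(target_train, standardizer) if standardizer
             else target_train.to_array())  # labels deliberately untouched

    ext_params = (model.branch_parameters() + model.fusion_parameters()
                  + model.head.parameters())
    opt_ext = Adam(ext_params, lr_extractor)
    opt_disc = Adam(model.discriminator_parameters(), lr_discriminator)
    scheduler = CosineAnnealing([opt_ext, opt_disc], epochs)
    rng = np.random.default_rng(derive_seed(seed, "stage2/batches"))

    n_s, n_t = len(x_src), len(x_tgt)
    steps = math.ceil(max(n_s, n_t) / batch_size)

    def batch_stream(n):
        while True:
            for i in rng.permutation(n).reshape(-1):
                yield i

    src_stream, tgt_stream = batch_stream(n_s), batch_stream(n_t)
    for epoch in range(epochs):
        scheduler.set_epoch(epoch)
        lam_local, lam_global = adv_cfg.lambdas_at(epoch, epochs)
        model.train()
        epoch_loss = 0.0
        for _ in range(steps):
            si = np.array([next(src_stream) for _ in range(batch_size)])
            ti = np.array([next(tgt_stream) for _ in range(batch_size)])
            # one joint forward so batch-norm statistics are shared across
            # domains; per-domain batches would pre-align the feature
            # distributions and starve the discriminators
            bundle = model(np.concatenate([x_src[si], x_tgt[ti]]))
            l_cls = obj.smoothed_cross_entropy(
                bundle.logits[:batch_size], y_src[si],
                loss_cfg.label_smoothing, model.n_classes)
            zero = Tensor(0.0)
            l_local = (obj.domain_adversarial_loss(
                bundle.f_cnn[:batch_size], bundle.f_cnn[batch_size:],
                model.disc_local, lam_local)
                if "local" in granularities and bundle.f_cnn is not None else zero)
            l_global = (obj.domain_adversarial_loss(
                bundle.f_attn[:batch_size], bundle.f_attn[batch_size:],
                model.disc_global, lam_global)
                if "global" in granularities and bundle.f_attn is not None else zero)
            loss = obj.stage2_loss(l_cls, l_local, l_global, loss_cfg.domain_weight)
            opt_ext.zero_grad()
            opt_disc.zero_grad()
            loss.backward()
            opt_ext.step()
            opt_disc.step()
            epoch_loss += loss.item()
        if log is not None:
            log.append({"stage": "align", "epoch": epoch,
                        "lambda_local": lam_local, "lambda_global": lam_global,
                        "loss": epoch_loss / steps})
    info = {"stage": "align", "seed": seed, "epochs": epochs,
            "granularities": list(granularities),
            "source_sample_ids": source.sample_ids,
            "target_sample_ids": target_train.sample_ids}
    return model, info


# ---------------------------------------------------------------------------
# stage 3: target fine-tuning
# ---------------------------------------------------------------------------

def finetune_target(
    model: MGDANet,
    target_train: LabeledDataset,
    n_target_classes: int,
    seed: int,
    epochs: int = DEFAULT_EPOCHS[2],
    batch_size: int = DEFAULT_BATCH_SIZE,
    lr_branches: float = STAGE3_LR_BRANCHES,
    lr_fusion: float = STAGE3_LR_FUSION,
    lr_head: float = STAGE3_LR_HEAD,
    val_fraction: float = 0.2,
    loss_cfg: obj.LossConfig | None = None,
    freeze_bn: bool = False,
    standardizer: Standardizer | None = None,
    log: list | None = None,
) -> tuple[MGDANet, dict]:
    """Replace the head for the target label space and fine-tune end-to-end."""
    if target_train.n_classes != n_target_classes:
        raise ValueError("n_target_classes does not match the labeled target set")
    loss_cfg = loss_cfg or obj.LossConfig()
    model.replace_head(n_target_classes, derive_seed(seed, "stage3/head_init"))
    centers = obj.init_centers(n_target_classes)
    if freeze_bn:
        for _, child in _walk_modules(model):
            if hasattr(child, "frozen"):
                child.frozen = True

    fit_ds, val_ds = stratified_validation_split(
        target_train, val_fraction, derive_seed(seed, "stage3/val_split"))
    x_fit = standardize_dataset(fit_ds, standardizer) if standardizer else fit_ds.to_array()
    x_val = standardize_dataset(val_ds, standardizer) if standardizer else val_ds.to_array()
    y_fit, y_val = fit_ds.labels, val_ds.labels

    opts = []
    if model.branch_parameters():
        opts.append(Adam(model.branch_parameters(), lr_branches))
    if model.fusion_parameters():
        opts.append(Adam(model.fusion_parameters(), lr_fusion))
    opts.append(Adam(model.head.parameters(), lr_head))
    scheduler = CosineAnnealing(opts, epochs)
    rng = np.random.default_rng(derive_seed(seed, "stage3/batches"))

    best = {"val_accuracy": -1.0, "epoch": -1, "state": None}
    n = len(x_fit)
    for epoch in range(epochs):
        scheduler.set_epoch(epoch)
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            bundle = model(x_fit[idx])
            l_cls = obj.smoothed_cross_entropy(
                bundle.logits, y_fit[idx], loss_cfg.label_smoothing, n_target_classes)
            l_cen = obj.center_loss(bundle.h, y_fit[idx], centers)
            loss = obj.stage1_loss(l_cls, l_cen, loss_cfg.center_weight)
            for opt in opts:
                opt.zero_grad()
            loss.backward()
            for opt in opts:
                opt.step()
            centers = obj.update_centers(bundle.h.data, y_fit[idx], centers,
                                         loss_cfg.center_lr)
            epoch_loss += loss.item() * len(idx)
        val_acc = _accuracy(model, x_val, y_val)
        if log is not None:
            log.append({"stage": "finetune", "epoch": epoch,
                        "loss": epoch_loss / n, "val_accuracy": val_acc})
        if val_acc > best["val_accuracy"]:
            best.update(val_accuracy=val_acc, epoch=epoch, state=model.state_dict())
    model.load_state_dict(best["state"])
    info = {"stage": "finetune", "seed": seed, "selection_epoch": best["epoch"],
            "val_accuracy": best["val_accuracy"], "centers": centers,
            "fit_sample_ids": fit_ds.sample_ids, "val_sample_ids": val_ds.sample_ids}
    return model, info


def _walk_modules(module):
    yield "", module
    for name, child in module._children():
        yield from ((f"{name}.{sub}", m) for sub, m in _walk_modules(child))


# ---------------------------------------------------------------------------
# linear-probe evaluation for the "no fine-tuning" variant
# ---------------------------------------------------------------------------

def linear_probe_evaluate(model: MGDANet, target_train: LabeledDataset,
                          target_test: LabeledDataset, seed: int,
                          epochs: int = DEFAULT_EPOCHS[2],
                          batch_size: int = DEFAULT_BATCH_SIZE,
                          lr: float = STAGE3_LR_HEAD,
                          standardizer: Standardizer | None = None) -> MetricsReport:
    """Frozen-feature linear probe for the variant that skips fine-tuning.

    A model without target fine-tuning has a head for the wrong label space,
    so its direct predictions are meaningless.  The variant is therefore
    evaluated by a single linear layer trained on frozen fused features under
    the same budget as a stage-3 head (same optimizer, learning rate, epoch
    count and batching), so that the comparison with the fine-tuned variants
    isolates the missing stage rather than a difference in training budget.
    """
    from .nn import Linear
    from .nn.optim import Adam as AdamOpt

    model.eval()
    x_tr = (standardize_dataset(target_train, standardizer) if standardizer
            else target_train.to_array())
    x_te = (standardize_dataset(target_test, standardizer) if standardizer
            else target_test.to_array())
    f_tr = _batched_fused(model, x_tr)
    f_te = _batched_fused(model, x_te)
    y_tr = target_train.labels
    n_classes = target_test.n_classes

    rng = np.random.default_rng(derive_seed(seed, "probe/init"))
    head = Linear(f_tr.shape[1], n_classes, rng)
    opt = AdamOpt(head.parameters(), lr)
    sched = CosineAnnealing([opt], epochs)
    batch_rng = np.random.default_rng(derive_seed(seed, "probe/batches"))
    cfg = obj.LossConfig()
    for epoch in range(epochs):
        sched.set_epoch(epoch)
        order = batch_rng.permutation(len(f_tr))
        for i in range(0, len(f_tr), batch_size):
            idx = order[i : i + batch_size]
            loss = obj.smoothed_cross_entropy(
                head(Tensor(f_tr[idx])), y_tr[idx], cfg.label_smoothing, n_classes)
            opt.zero_grad()
            loss.backward()
            opt.step()
    with no_grad():
        y_pred = head(Tensor(f_te)).data.argmax(axis=1)
    return compute_metrics(target_test.labels, y_pred, n_classes)


def _batched_fused(model: MGDANet, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = []
    with no_grad():
        for i in range(0, len(x), batch_size):
            out.append(model(x[i : i + batch_size]).f_fused.data)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def run_transfer_experiment(
    source: LabeledDataset,
    target: LabeledDataset,
    split: SplitSpec,
    seed: int,
    epochs: tuple[int, int, int] = DEFAULT_EPOCHS,
    batch_size: int = DEFAULT_BATCH_SIZE,
    variant: str = "full",
    batch_sizes: tuple[int, int, int] | None = None,
    log: list | None = None,
) -> dict:
    """Run the full pipeline (or an ablation variant) once and evaluate."""
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")
    b1, b2, b3 = batch_sizes or (batch_size,) * 3

    branches = {"cnn_only": "cnn", "attn_only": "attn"}.get(variant, "both")
    fusion = "concat" if variant == "concat_fusion" else "adaptive"
    granularities = {
        "local_only_da": ("local",),
        "global_only_da": ("global",),
        "cnn_only": ("local",),
        "attn_only": ("global",),
    }.get(variant, ("local", "global"))

    tgt_train, tgt_test = day_wise_split(target, split)
    standardizer = fit_input_standardizer(source, "source_train")

    model, info1 = pretrain_source(
        source, seed, epochs=epochs[0], batch_size=b1,
        branches=branches, fusion=fusion, standardizer=standardizer, log=log)

    if variant != "no_da":
        model, info2 = adversarial_align(
            model, source, tgt_train, seed, epochs=epochs[1],
            batch_size=b2, granularities=granularities,
            standardizer=standardizer, log=log)
    else:
        info2 = {"stage": "align", "skipped": True}

    if variant == "no_finetune":
        report = linear_probe_evaluate(model, tgt_train, tgt_test, seed,
                                       epochs=epochs[2], batch_size=b3,
                                       standardizer=standardizer)
        info3 = {"stage": "finetune", "policy": "linear_probe"}
    else:
        model, info3 = finetune_target(
            model, tgt_train, target.n_classes, seed, epochs=epochs[2],
            batch_size=b3, standardizer=standardizer, log=log)
        report = evaluate(model, tgt_test, standardizer=standardizer)

    train_ids = set(tgt_train.sample_ids) | set(source.sample_ids)
    return {
        "variant": variant,
        "seed": seed,
        "metrics": report,
        "model": model,
        "standardizer": standardizer,
        "stage_infos": [info1, info2, info3],
        "train_sample_ids": sorted(train_ids),
        "test_sample_ids": tgt_test.sample_ids,
    }


def run_ablation(variant: str, source: LabeledDataset, target: LabeledDataset,
                 split: SplitSpec, seeds: list[int],
                 epochs: tuple[int, int, int] = DEFAULT_EPOCHS,
                 batch_size: int = DEFAULT_BATCH_SIZE) -> ExperimentResult:
    """Evaluate one ablation variant over multiple seeds."""
    reports = [
        run_transfer_experiment(source, target, split, s, epochs=epochs,
                                batch_size=batch_size, variant=variant)["metrics"]
        for s in seeds
    ]
    return ExperimentResult(variant, list(seeds), reports)


def run_label_efficiency(
    source: LabeledDataset,
    target: LabeledDataset,
    split: SplitSpec,
    ratios: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2),
    seeds: list[int] = tuple(range(10)),
    epochs: tuple[int, int, int] = DEFAULT_EPOCHS,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> pd.DataFrame:
    """Hold Stages 1-2 fixed per seed; repeat Stage 3 at reduced label ratios."""
    tgt_train, tgt_test = day_wise_split(target, split)
    standardizer = fit_input_standardizer(source, "source_train")
    rows = []
    for seed in seeds:
        model, _ = pretrain_source(source, seed, epochs=epochs[0],
                                   batch_size=batch_size, standardizer=standardizer)
        model, _ = adversarial_align(model, source, tgt_train, seed,
                                     epochs=epochs[1], batch_size=batch_size,
                                     standardizer=standardizer)
        aligned_state = model.state_dict()
        for ratio in ratios:
            sub = stratified_subsample(tgt_train, ratio,
                                       derive_seed(seed, f"subsample/{ratio}"))
            # fresh copy of the aligned model (Stage 3 replaces the head in place)
            trial = MGDANet(source.n_classes,
                            seed=derive_seed(seed, "stage1/init"))
            trial.load_state_dict(aligned_state)
            trial, _ = finetune_target(trial, sub, target.n_classes, seed,
                                       epochs=epochs[2], batch_size=batch_size,
                                       standardizer=standardizer)
            report = evaluate(trial, tgt_test, standardizer=standardizer)
            rows.append({"ratio": ratio, "labeled": len(sub), "seed": seed,
                         "overall_accuracy": report.overall_accuracy,
                         "f1_macro": report.f1_macro, "kappa": report.kappa})
    df = pd.DataFrame(rows)
    return df


def run_variant_suite(
    source: LabeledDataset,
    target: LabeledDataset,
    split: SplitSpec,
    seed: int,
    epochs: tuple[int, int, int] = DEFAULT_EPOCHS,
    batch_sizes: tuple[int, int, int] = (DEFAULT_BATCH_SIZE,) * 3,
    label_ratios: tuple[float, ...] = (),
    mmd_levels: tuple[str, ...] = ("local", "global"),
) -> dict:
    """One seed of the full experiment grid with shared stages.

    Variants that share an architecture and an unablated stage reuse that
    stage's checkpoint instead of retraining it: the full model, both
    single-granularity alignment variants, the no-alignment variant and the
    no-fine-tuning probe all share Stage 1; the probe and the label-ratio
    runs also share the full Stage 2.  Per-branch domain discrepancy
    (multi-kernel MMD) is measured after Stage 1 and after Stage 2.

    Returns a dict with per-variant accuracy/metrics, MMD reports, and
    label-efficiency rows for ``label_ratios``.
    """
    from .analysis import domain_mmd_report  # local import to avoid a cycle

    b1, b2, b3 = batch_sizes
    tgt_train, tgt_test = day_wise_split(target, split)
    standardizer = fit_input_standardizer(source, "source_train")
    x_src = standardize_dataset(source, standardizer)
    x_tt = standardize_dataset(tgt_train, standardizer)

    def fresh_from(state):
        m = MGDANet(source.n_classes, seed=derive_seed(seed, "stage1/init"))
        m.load_state_dict(state)
        return m

    def stage3(m):
        m, _ = finetune_target(m, tgt_train, target.n_classes, seed,
                               epochs=epochs[2], batch_size=b3,
                               standardizer=standardizer)
        return evaluate(m, tgt_test, standardizer=standardizer)

    results: dict = {"seed": seed, "metrics": {}, "mmd": {}, "label_efficiency": []}

    # shared Stage 1 (full architecture)
    model, _ = pretrain_source(source, seed, epochs=epochs[0], batch_size=b1,
                               standardizer=standardizer)
    state1 = model.state_dict()
    results["mmd"]["after_stage1"] = {
        r.level: r.combined
        for r in domain_mmd_report(model, x_src, x_tt, "after_stage1", mmd_levels)}

    # full pipeline + everything sharing its Stage 2
    m2, _ = adversarial_align(fresh_from(state1), source, tgt_train, seed,
                              epochs=epochs[1], batch_size=b2,
                              standardizer=standardizer)
    state2 = m2.state_dict()
    results["mmd"]["after_stage2"] = {
        r.level: r.combined
        for r in domain_mmd_report(m2, x_src, x_tt, "after_stage2", mmd_levels)}
    results["metrics"]["full"] = stage3(fresh_from(state2))
    results["metrics"]["no_finetune"] = linear_probe_evaluate(
        fresh_from(state2), tgt_train, tgt_test, seed, epochs=epochs[2],
        batch_size=b3, standardizer=standardizer)
    results["metrics"]["no_da"] = stage3(fresh_from(state1))

    for variant, grans in (("local_only_da", ("local",)),
                           ("global_only_da", ("global",))):
        mg, _ = adversarial_align(fresh_from(state1), source, tgt_train, seed,
                                  epochs=epochs[1], batch_size=b2,
                                  granularities=grans, standardizer=standardizer)
        results["metrics"][variant] = stage3(mg)

    # architecture ablations need their own pipelines end to end
    for variant in ("cnn_only", "attn_only", "concat_fusion"):
        results["metrics"][variant] = run_transfer_experiment(
            source, target, split, seed, epochs=epochs,
            batch_sizes=batch_sizes, variant=variant)["metrics"]

    for ratio in label_ratios:
        if ratio == 1.0:
            report = results["metrics"]["full"]
            sub_n = len(tgt_train)
        else:
            sub = stratified_subsample(tgt_train, ratio,
                                       derive_seed(seed, f"subsample/{ratio}"))
            trial, _ = finetune_target(fresh_from(state2), sub, target.n_classes,
                                       seed, epochs=epochs[2], batch_size=b3,
                                       standardizer=standardizer)
            report = evaluate(trial, tgt_test, standardizer=standardizer)
            sub_n = len(sub)
        results["label_efficiency"].append(
            {"ratio": ratio, "labeled": sub_n, "seed": seed,
             "overall_accuracy": report.overall_accuracy})
    return results


def summarize_label_efficiency(df: pd.DataFrame) -> pd.DataFrame:
    return (df.groupby("ratio")
              .agg(labeled=("labeled", "first"),
                   accuracy_mean=("overall_accuracy", "mean"),
                   accuracy_sd=("overall_accuracy", "std"),
                   f1_mean=("f1_macro", "mean"),
                   kappa_mean=("kappa", "mean"))
              .reset_index()
              .sort_values("ratio", ascending=False, ignore_index=True))
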