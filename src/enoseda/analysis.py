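"""Feature-space analyses: steady-state PCA, multi-kernel MMD, exports.

Steady-state features summarise each measurement by the mean response of each
sensor over the final 20 time steps of the 120-step window — the near-plateau
region of the exposure curve.  Domain discrepancy between source and target
feature clouds is quantified with a multi-kernel maximum mean discrepancy:
five Gaussian kernels whose bandwidths are the median pairwise squared
distance of the pooled sample scaled by {0.25, 0.5, 1, 2, 4}, combined by
averaging the per-kernel MMD^2 values.  The biased (V-statistic) estimator is
the default so reported values are non-negative; the unbiased U-statistic is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .datamodel import LabeledDataset, N_TIMESTEPS, STD_FLOOR
from .network import MGDANet

STEADY_STATE_WINDOW = 20  # final time steps averaged per channel
BANDWIDTH_FACTORS = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class MMDReport:
    level: str  # local | global | fused
    stage: str  # after_stage1 | after_stage2
    bandwidths: np.ndarray
    per_kernel_mmd2: np.ndarray
    combined: float

    def to_dict(self) -> dict:
        return {"level": self.level, "stage": self.stage,
                "bandwidths": self.bandwidths.tolist(),
                "per_kernel_mmd2": self.per_kernel_mmd2.tolist(),
                "combined": self.combined}


def steady_state_features(ds: LabeledDataset) -> np.ndarray:
    """Per-sample 10-vector: channel means over the last 20 time steps."""
    x = ds.to_array()
    return x[:, :, N_TIMESTEPS - STEADY_STATE_WINDOW :].mean(axis=2)


def pca_summary(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns then PCA; returns (explained variance ratios, scores)."""
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for a PCA summary")
    z = (features - features.mean(axis=0)) / np.maximum(features.std(axis=0), STD_FLOOR)
    pca = PCA()
    scores = pca.fit_transform(z)
    return pca.explained_variance_ratio_, scores


def multikernel_mmd(fs: np.ndarray, ft: np.ndarray,
                    bandwidth_factors: tuple[float, ...] = BANDWIDTH_FACTORS,
                    level: str = "fused", stage: str = "after_stage1",
                    unbiased: bool = False) -> MMDReport:
    """Multi-kernel MMD^2 between two feature clouds.

    Base bandwidth = median pairwise squared distance over the pooled sample;
    per kernel, MMD^2 = mean(K_ss) + mean(K_tt) - 2 mean(K_st); the report's
    ``combined`` value is the mean over kernels.
    """
    fs, ft = np.atleast_2d(np.asarray(fs, float)), np.atleast_2d(np.asarray(ft, float))
    if fs.shape[0] < 2 or ft.shape[0] < 2:
        raise ValueError("need at least 2 samples on each side")
    pooled = np.vstack([fs, ft])
    d2 = cdist(pooled, pooled, "sqeuclidean")
    base = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    base = max(base, STD_FLOOR)
    bandwidths = base * np.asarray(bandwidth_factors)

    n_s, n_t = fs.shape[0], ft.shape[0]
    d_ss = d2[:n_s, :n_s]
    d_tt = d2[n_s:, n_s:]
    d_st = d2[:n_s, n_s:]
    per_kernel = []
    for bw in bandwidths:
        k_ss, k_tt, k_st = (np.exp(-d / bw) for d in (d_ss, d_tt, d_st))
        if unbiased:
            term_ss = (k_ss.sum() - np.trace(k_ss)) / (n_s * (n_s - 1))
            term_tt = (k_tt.sum() - np.trace(k_tt)) / (n_t * (n_t - 1))
        else:
            term_ss, term_tt = k_ss.mean(), k_tt.mean()
        per_kernel.append(term_ss + term_tt - 2.0 * k_st.mean())
    per_kernel = np.array(per_kernel)
    return MMDReport(level, stage, bandwidths, per_kernel, float(per_kernel.mean()))


def extract_level_features(model: MGDANet, x: np.ndarray, level: str,
                           batch_size: int = 64) -> np.ndarray:
    """Inference-mode features at one tap point: local/global (128) or fused (256)."""
    if level not in ("local", "global", "fused"):
        raise ValueError(f"unknown feature level {level!r}")
    model.eval()
    out = []
    from .nn import no_grad
    with no_grad():
        for i in range(0, len(x), batch_size):
            bundle = model(x[i : i + batch_size])
            feat = {"local": bundle.f_cnn, "global": bundle.f_attn,
                    "fused": bundle.f_fused}[level]
            if feat is None:
                raise ValueError(f"model variant has no {level!r} feature")
            out.append(feat.data)
    return np.concatenate(out)


def domain_mmd_report(model: MGDANet, x_source: np.ndarray, x_target: np.ndarray,
                      stage: str, levels=("local", "global", "fused")) -> list[MMDReport]:
    """MMD between source and target training features at each tap point."""
    return [
        multikernel_mmd(extract_level_features(model, x_source, lv),
                        extract_level_features(model, x_target, lv),
                        level=lv, stage=stage)
        for lv in levels
    ]


def export_embeddings(features: np.ndarray, class_labels, domains,
                      path: str | Path) -> pd.DataFrame:
    """Write a feature matrix + class/domain columns as CSV for external 2-D
    embedding tools; returns the written frame."""
    features = np.asarray(features, dtype=np.float64)
    class_labels = np.asarray(class_labels)
    if len(features) != len(class_labels) or len(features) != len(domains):
        raise ValueError("features, class labels and domains must align")
    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    df["class_label"] = class_labels
    df["domain"] = list(domains)
    df.to_csv(path, index=False, float_format="%.17g")
    return df
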