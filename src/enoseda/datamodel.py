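"""Core data types, normalisation and dataset-splitting logic.

An electronic-nose measurement is a 10-sensor x 120-time-step conductance
matrix with class, domain and acquisition-day metadata.  This module owns the
operations every experiment builds on: per-channel instance normalisation,
day-wise train/test partitioning (test sessions never seen in training),
stratified validation splits and stratified subsampling for label-efficiency
studies, and train-set-only feature standardisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

N_SENSORS = 10
N_TIMESTEPS = 120
#: variance floor for per-channel instance normalisation (constant rows -> 0)
INSTANCE_NORM_VAR_FLOOR = 1e-5
#: floor applied to any standard deviation before division
STD_FLOOR = 1e-8


@dataclass
class ENoseMeasurement:
    """One sensor-array acquisition: a C x T response matrix plus metadata."""

    values: np.ndarray
    sample_id: str
    class_label: int
    domain_tag: str  # "source" | "target"
    day: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_SENSORS, N_TIMESTEPS):
            raise ValueError(
                f"measurement {self.sample_id!r} has shape {self.values.shape}, "
                f"expected ({N_SENSORS}, {N_TIMESTEPS})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"measurement {self.sample_id!r} contains non-finite values")
        if self.class_label < 0:
            raise ValueError("class_label must be >= 0")
        if self.domain_tag not in ("source", "target"):
            raise ValueError("domain_tag must be 'source' or 'target'")
        if self.day < 1:
            raise ValueError("day is 1-based and must be >= 1")


@dataclass
class LabeledDataset:
    measurements: list[ENoseMeasurement]
    class_names: list[str]
    n_classes: int = 0

    def __post_init__(self):
        if not self.n_classes:
            self.n_classes = len(self.class_names)
        for m in self.measurements:
            if m.class_label >= self.n_classes:
                raise ValueError(
                    f"class_label {m.class_label} out of range for {self.n_classes} classes"
                )

    def __len__(self) -> int:
        return len(self.measurements)

    def to_array(self) -> np.ndarray:
        return np.stack([m.values for m in self.measurements])

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.class_label for m in self.measurements], dtype=np.int64)

    @property
    def days(self) -> np.ndarray:
        return np.array([m.day for m in self.measurements], dtype=np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.measurements]

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.measurements[i] for i in indices],
                              self.class_names, self.n_classes)

    def class_counts(self) -> dict[int, int]:
        counts = {c: 0 for c in range(self.n_classes)}
        for m in self.measurements:
            counts[m.class_label] += 1
        return counts


@dataclass
class SplitSpec:
    train_days: set[int]
    test_days: set[int]
    val_fraction: float = 0.2
    subsample_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.train_days = set(self.train_days)
        self.test_days = set(self.test_days)
        if self.train_days & self.test_days:
            raise ValueError("train_days and test_days must be disjoint")
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must be in [0, 1)")
        if not (0 < self.subsample_ratio <= 1):
            raise ValueError("subsample_ratio must be in (0, 1]")


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics frozen on a training set."""

    per_feature_mean: np.ndarray
    per_feature_std: np.ndarray
    fitted_on: str = "source_train"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def instance_normalize(m: ENoseMeasurement) -> ENoseMeasurement:
    """Z-score each sensor channel over its own time axis (population stats).

    Removes sensor-level offset/scale variability; a constant channel maps to
    all zeros via the variance floor.  No learnable affine follows, since that
    would reintroduce exactly the per-sensor variability being removed.
    """
    values = instance_normalize_array(m.values[None])[0]
    return ENoseMeasurement(values, m.sample_id, m.class_label, m.domain_tag, m.day)


def instance_normalize_array(x: np.ndarray) -> np.ndarray:
    """Vectorised instance normalisation over a (n, C, T) stack."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(np.maximum(var, INSTANCE_NORM_VAR_FLOOR))


def day_wise_split(ds: LabeledDataset, spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition by acquisition day so test sessions are unseen in training."""
    allowed = spec.train_days | spec.test_days
    for m in ds.measurements:
        if m.day not in allowed:
            raise ValueError(f"measurement {m.sample_id!r} has day {m.day}, "
                             f"which is in neither train_days nor test_days")
    train_idx = [i for i, m in enumerate(ds.measurements) if m.day in spec.train_days]
    test_idx = [i for i, m in enumerate(ds.measurements) if m.day in spec.test_days]
    return ds.subset(train_idx), ds.subset(test_idx)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _largest_remainder_counts(class_sizes: dict[int, int], total: int,
                              rng: np.random.Generator) -> dict[int, int]:
    """Allocate ``total`` over classes proportionally, remainders to the
    largest fractional parts with seed-shuffled tie order."""
    n = sum(class_sizes.values())
    classes = sorted(class_sizes)
    exact = {c: total * class_sizes[c] / n for c in classes}
    counts = {c: int(np.floor(exact[c])) for c in classes}
    leftover = total - sum(counts.values())
    order = list(classes)
    rng.shuffle(order)
    order.sort(key=lambda c: -(exact[c] - counts[c]))  # stable: ties keep shuffle order
    for c in order[:leftover]:
        counts[c] += 1
    return counts


def stratified_validation_split(
    train: LabeledDataset, frac: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split off a stratified validation subset; deterministic given seed."""
    if not (0 < frac < 1):
        raise ValueError("frac must be strictly between 0 and 1")
    counts = train.class_counts()
    for c, k in counts.items():
        if k < 2:
            raise ValueError(f"class {c} has {k} sample(s); need >= 2 to split")
    rng = np.random.default_rng(seed)
    total_val = _round_half_up(frac * len(train))
    per_class = _largest_remainder_counts(counts, total_val, rng)
    val_idx: list[int] = []
    labels = train.labels
    for c in sorted(counts):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        val_idx.extend(idx[: per_class[c]].tolist())
    val_set = set(val_idx)
    fit_idx = [i for i in range(len(train)) if i not in val_set]
    return train.subset(fit_idx), train.subset(sorted(val_idx))


def stratified_subsample(train: LabeledDataset, ratio: float, seed: int) -> LabeledDataset:
    """Retain round-half-up(ratio * n) samples with per-class balance +/-1."""
    if not (0 < ratio <= 1):
        raise ValueError("ratio must be in (0, 1]")
    if ratio == 1.0:
        return train
    rng = np.random.default_rng(seed)
    counts = train.class_counts()
    total = _round_half_up(ratio * len(train))
    per_class = _largest_remainder_counts(counts, total, rng)
    for c, k in per_class.items():
        if k == 0 and counts[c] > 0:
            raise ValueError(f"ratio {ratio} empties class {c}")
    keep: list[int] = []
    labels = train.labels
    for c in sorted(counts):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        keep.extend(idx[: per_class[c]].tolist())
    return train.subset(sorted(keep))


def fit_standardizer(features: np.ndarray, fitted_on: str = "source_train") -> Standardizer:
    features = np.asarray(features, dtype=np.float64)
    if features.size == 0:
        raise ValueError("cannot fit a standardizer on an empty matrix")
    mean = features.mean(axis=0)
    std = features.std(axis=0)
    return Standardizer(mean, np.maximum(std, STD_FLOOR), fitted_on)


def apply_standardizer(s: Standardizer, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=np.float64)
    if features.shape[-1] != s.per_feature_mean.shape[0]:
        raise ValueError(
            f"feature count {features.shape[-1]} does not match fitted "
            f"{s.per_feature_mean.shape[0]}"
        )
    return (features - s.per_feature_mean) / s.per_feature_std


# ---------------------------------------------------------------------------
# I/O: long-format CSV, HDF5, and split manifests
# ---------------------------------------------------------------------------

def dataset_to_frame(ds: LabeledDataset) -> pd.DataFrame:
    n = len(ds)
    s_idx, t_idx = np.meshgrid(np.arange(N_SENSORS), np.arange(N_TIMESTEPS), indexing="ij")
    rows = []
    for m in ds.measurements:
        rows.append(pd.DataFrame({
            "sample_id": m.sample_id,
            "domain": m.domain_tag,
            "class_label": m.class_label,
            "day": m.day,
            "sensor_index": s_idx.ravel(),
            "time_index": t_idx.ravel(),
            "value": m.values.ravel(),
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", "domain", "class_label", "day",
                 "sensor_index", "time_index", "value"])


def write_csv(ds: LabeledDataset, path: str | Path):
    dataset_to_frame(ds).to_csv(path, index=False)


def read_csv(path: str | Path, class_names: list[str] | None = None) -> LabeledDataset:
    df = pd.read_csv(path)
    measurements = []
    for sid, grp in df.groupby("sample_id", sort=False):
        values = np.zeros((N_SENSORS, N_TIMESTEPS))
        values[grp["sensor_index"], grp["time_index"]] = grp["value"]
        measurements.append(ENoseMeasurement(
            values, str(sid), int(grp["class_label"].iloc[0]),
            str(grp["domain"].iloc[0]), int(grp["day"].iloc[0])))
    n_classes = int(df["class_label"].max()) + 1
    names = class_names or [f"class_{i}" for i in range(n_classes)]
    return LabeledDataset(measurements, names, n_classes)


def write_hdf5(ds: LabeledDataset, path: str | Path, name: str = "measurements"):
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_dataset(name, data=ds.to_array())
        g.attrs["class_label"] = ds.labels
        g.attrs["day"] = ds.days
        g.attrs["domain"] = [m.domain_tag for m in ds.measurements]
        g.attrs["sample_id"] = ds.sample_ids
        g.attrs["class_names"] = ds.class_names


def read_hdf5(path: str | Path, name: str = "measurements") -> LabeledDataset:
    with h5py.File(path, "r") as f:
        g = f[name]
        values = np.array(g)
        labels = np.array(g.attrs["class_label"])
        days = np.array(g.attrs["day"])
        domains = [d.decode() if isinstance(d, bytes) else str(d) for d in g.attrs["domain"]]
        sids = [s.decode() if isinstance(s, bytes) else str(s) for s in g.attrs["sample_id"]]
        names = [c.decode() if isinstance(c, bytes) else str(c) for c in g.attrs["class_names"]]
    ms = [ENoseMeasurement(values[i], sids[i], int(labels[i]), domains[i], int(days[i]))
          for i in range(len(values))]
    return LabeledDataset(ms, names, len(names))


def write_split_manifest(path: str | Path, spec: SplitSpec,
                         partitions: dict[str, LabeledDataset]):
    manifest = {
        "spec": {
            "train_days": sorted(spec.train_days),
            "test_days": sorted(spec.test_days),
            "val_fraction": spec.val_fraction,
            "subsample_ratio": spec.subsample_ratio,
            "seed": spec.seed,
        },
        "partitions": {k: v.sample_ids for k, v in partitions.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_split_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
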