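"""Experiment configuration: YAML-backed, validated, hashable.

One config file drives a whole experiment: the synthetic benchmark settings,
the day-wise split, the per-stage epoch counts, loss weights and the seed
list.  Defaults reproduce the protocol's stated hyperparameters (epochs
200/200/300; learning rates 1e-3, 2e-4 + 1e-3, and 3e-5/5e-5/1e-4; label
smoothing 0.05; center weight 0.01; domain weight 0.5; reversal maxima
0.2/0.1).  Every result file records the config hash that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .objectives import AdversarialConfig, LossConfig


@dataclass
class BenchmarkSettings:
    difficulty: float = 0.5
    n_source_classes: int = 12
    n_target_classes: int = 6
    source_per_day: int = 10
    source_days: int = 12
    target_per_day: int = 6
    target_days: int = 10


@dataclass
class SplitSettings:
    train_days: list[int] = field(default_factory=lambda: list(range(1, 9)))
    test_days: list[int] = field(default_factory=lambda: [9, 10])
    val_fraction: float = 0.2


#: Reduced-scale study conditions used by the directional experiment suite
#: (and the reproduction script): a 12-class source acquired over 4 days
#: (2 per class per day, 96 measurements), a fine-grained 6-class target over
#: 5 days (4 per class per day; days 1-3 train, 4-5 test), a strong domain
#: shift, and shortened stages.  Chosen once for desk-scale runs and frozen;
#: see docs/methods.md.
REDUCED_SCALE = {
    "benchmark": {
        "difficulty": 1.0,
        "n_source_classes": 12,
        "n_target_classes": 6,
        "source_per_day": 2,
        "source_days": 4,
        "target_per_day": 4,
        "target_days": 5,
        "target_separation": 0.65,
    },
    "train_days": {1, 2, 3},
    "test_days": {4, 5},
    "epochs": (15, 12, 30),
    "batch_sizes": (16, 16, 8),
    "label_ratios": (1.0, 0.6, 0.2),
    "seeds": (1, 2, 3),
}


@dataclass
class ExperimentConfig:
    benchmark: BenchmarkSettings = field(default_factory=BenchmarkSettings)
    split: SplitSettings = field(default_factory=SplitSettings)
    epochs: tuple[int, int, int] = (200, 200, 300)
    batch_size: int = 32
    losses: LossConfig = field(default_factory=LossConfig)
    adversarial: AdversarialConfig = field(default_factory=AdversarialConfig)
    seeds: list[int] = field(default_factory=lambda: list(range(10)))
    output_dir: str = "runs"

    def validate(self):
        checks = [
            ("benchmark.difficulty", 0.0 <= self.benchmark.difficulty <= 1.0),
            ("split.train_days/test_days",
             not set(self.split.train_days) & set(self.split.test_days)),
            ("split.val_fraction", 0 < self.split.val_fraction < 1),
            ("epochs", len(self.epochs) == 3 and all(e >= 1 for e in self.epochs)),
            ("batch_size", self.batch_size >= 1),
            ("seeds", len(self.seeds) >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid configuration field: {name}")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epochs"] = list(self.epochs)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        cfg = cls()
        if "benchmark" in d:
            cfg.benchmark = BenchmarkSettings(**d["benchmark"])
        if "split" in d:
            cfg.split = SplitSettings(**d["split"])
        if "losses" in d:
            cfg.losses = LossConfig(**d["losses"])
        if "adversarial" in d:
            cfg.adversarial = AdversarialConfig(**d["adversarial"])
        for key in ("epochs", "batch_size", "seeds", "output_dir"):
            if key in d:
                setattr(cfg, key, tuple(d[key]) if key == "epochs" else d[key])
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls.from_dict(data)
        except TypeError as exc:  # unknown field name inside a section
            raise ValueError(f"invalid configuration: {exc}") from exc

    def write_manifest(self, path: str | Path, **extra):
        manifest = {"config": self.to_dict(), "config_hash": self.config_hash()}
        manifest.update(extra)
        Path(path).write_text(json.dumps(manifest, indent=2))
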