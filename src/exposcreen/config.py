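"""Pipeline configuration: one YAML document with per-stage sections.

All screening thresholds are surfaced as named keys with their standard
defaults (blank ratio 2, detection threshold 5000, duplicate tolerances
15 ppm / 0.5 min, formula-match tolerance 5 ppm with score threshold 70,
zero substitution 0.1) and validated before any stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .synth import (
    DEFAULT_BATCH_PLAN,
    EffectsConfig,
    FeatureGenConfig,
    WristbandConfig,
)


@dataclass
class Thresholds:
    blank_ratio: float = 2.0
    detection_threshold: float = 5000.0
    match_ppm: float = 5.0
    score_threshold: float = 70.0
    dup_ppm: float = 15.0
    dup_rt: float = 0.5
    zero_sub: float = 0.1
    alpha: float = 0.05


@dataclass
class DbConfig:
    n_formulas: int = 300
    max_isomers: int = 6


@dataclass
class CohortConfig:
    n_per_city: int = 75


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    db: DbConfig = field(default_factory=DbConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    batch_plan: dict = field(
        default_factory=lambda: {c: list(b) for c, b in DEFAULT_BATCH_PLAN.items()}
    )
    effects: EffectsConfig = field(default_factory=EffectsConfig)
    feature_gen: FeatureGenConfig = field(default_factory=FeatureGenConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    wristband: WristbandConfig = field(default_factory=WristbandConfig)
    n_wristband_participants: int = 26
    matrices: list = field(default_factory=lambda: ["maternal", "cord"])
    drop_unreplicated_across_batches: bool = False
    ratio_on_corrected: bool = True
    make_figures: bool = False
    n_matching_repeats: int = 3

    def validate(self) -> None:
        problems = []
        t = self.thresholds
        for name in ("blank_ratio", "detection_threshold", "match_ppm",
                     "score_threshold", "dup_ppm", "dup_rt", "zero_sub"):
            if getattr(t, name) <= 0:
                problems.append(f"thresholds.{name} must be positive")
        if not 0 < t.alpha < 1:
            problems.append("thresholds.alpha must lie in (0,1)")
        if self.db.n_formulas < 1 or self.db.max_isomers < 1:
            problems.append("db sizes must be >= 1")
        if self.cohort.n_per_city < 1:
            problems.append("cohort.n_per_city must be >= 1")
        for m in self.matrices:
            if m not in ("maternal", "cord"):
                problems.append(f"unknown matrix {m!r}")
        if not self.batch_plan:
            problems.append("batch_plan must not be empty")
        if problems:
            raise ConfigError("invalid configuration:\n- " + "\n- ".join(problems))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        kwargs = {}
        nested = {
            "db": DbConfig,
            "cohort": CohortConfig,
            "effects": EffectsConfig,
            "feature_gen": FeatureGenConfig,
            "thresholds": Thresholds,
            "wristband": WristbandConfig,
        }
        for key, sub in d.items():
            if key in nested:
                fields = {f.name for f in dataclasses.fields(nested[key])}
                unknown = set(sub) - fields
                if unknown:
                    raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                sub = {
                    k: (tuple(v) if isinstance(v, list) and
                        isinstance(getattr(nested[key](), k), tuple) else v)
                    for k, v in sub.items()
                }
                if key == "effects" and "batch_shift" in sub:
                    sub["batch_shift"] = {
                        int(k): float(v) for k, v in sub["batch_shift"].items()
                    }
                kwargs[key] = nested[key](**sub)
            elif key == "batch_plan":
                kwargs[key] = {c: list(b) for c, b in sub.items()}
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = sub
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
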