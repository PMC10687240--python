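"""Run configuration: one structured YAML file drives the whole pipeline.

Every stochastic stage receives a seed derived deterministically from
the global seed and the stage name, so a run is fully regenerable from
config + seed alone.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % 2_147_483_647


@dataclass
class CohortSection:
    n_participants: int = 1000
    n_steps: int = 7
    n_features: int = 12
    n_informative: int = 5
    target_prevalence_first: float = 0.04
    target_prevalence_last: float = 0.16
    missing_rate_lo: float = 0.05
    missing_rate_hi: float = 0.30


@dataclass
class ImputationSection:
    method: str = "brits"
    epochs: int = 40
    hidden_size: int = 16
    learning_rate: float = 0.01
    batch_size: int = 256
    consistency_weight: float = 0.1


@dataclass
class SelectionSection:
    family: str = "linear"
    layout: str = "per_step"
    cv_folds: int = 5
    max_missing: float = 0.8


@dataclass
class WindowingSection:
    n: int = 3


@dataclass
class TrainingSection:
    batch_size: int = 32
    dropout: float = 0.2
    n_layers: int = 2
    hidden_size: int = 16
    max_epochs: int = 12
    patience: int = 4
    learning_rate: float = 0.005
    optimizer_name: str = "adam"
    cell_kind: str = "lstm"


@dataclass
class EvaluationSection:
    n_repetitions: int = 3
    n_folds: int = 5
    threshold: float = 0.5
    include_pair_family: bool = True
    include_recurrent_baselines: bool = True


@dataclass
class RunConfig:
    seed: int = 1
    output_dir: str = "runs/default"
    cohort: CohortSection = field(default_factory=CohortSection)
    imputation: ImputationSection = field(default_factory=ImputationSection)
    selection: SelectionSection = field(default_factory=SelectionSection)
    windowing: WindowingSection = field(default_factory=WindowingSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "cohort": CohortSection,
            "imputation": ImputationSection,
            "selection": SelectionSection,
            "windowing": WindowingSection,
            "training": TrainingSection,
            "evaluation": EvaluationSection,
        }
        known_top = {f.name for f in fields(cls)}
        bad = sorted(set(raw) - known_top)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        kwargs = {}
        for name, sec_cls in sections.items():
            sec_raw = raw.get(name, {}) or {}
            known = {f.name for f in fields(sec_cls)}
            bad = sorted(set(sec_raw) - known)
            if bad:
                raise ValueError(f"unknown config keys in section {name!r}: {bad}")
            kwargs[name] = sec_cls(**sec_raw)
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "output_dir" in raw:
            kwargs["output_dir"] = str(raw["output_dir"])
        return cls(**kwargs)
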