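"""Experiment configuration: one flat YAML document drives everything.

Unknown keys are rejected (typos should fail loudly), missing keys fall
back to documented defaults that reproduce the reference settings where
stated (3000 mm presence threshold, the 13-value confidence-threshold
grid, 4 rounds, ablation fractions 10/25/50/75/90%).  All randomness in a
run derives from ``master_seed``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import AugmentationParams, ClassifierSpec, TrainingSchedule
from .errors import ConfigurationError
from .pseudolabel import ThresholdGrid
from .synth import CaptureConfig, SplitPlan

log = logging.getLogger("herdid")


@dataclass
class ExperimentConfig:
    generator: CaptureConfig = field(default_factory=CaptureConfig)
    split_plan: SplitPlan = field(default_factory=SplitPlan)
    threshold_mm: float = 3000.0
    padding: int = 2
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    n_rounds: int = 4
    ablation_fractions: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 0.90)
    master_seed: int = 0
    outdir: str = "herdid_run"


_SECTION_TYPES = {
    "generator": CaptureConfig,
    "split_plan": SplitPlan,
    "classifier": ClassifierSpec,
    "schedule": TrainingSchedule,
    "augmentation": AugmentationParams,
}
_TUPLE_FIELDS = {
    "days", "train_days", "val_days", "test_days", "unlabeled_days",
    "brightness_jitter", "day_illumination_range", "input_hw",
    "brightness_range", "ablation_fractions", "channels",
}


def _build_section(cls, payload: dict, path: str):
    if not isinstance(payload, dict):
        raise ConfigurationError(f"section '{path}' must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(payload) - known)
    if unknown:
        raise ConfigurationError(f"unknown key(s) under '{path}': {', '.join(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in payload.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a YAML config; unknown keys are errors, missing keys get defaults."""
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:  # surface the line number
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigurationError(f"cannot parse {path}{where}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigurationError(f"{path} must contain a mapping at top level")

    top_known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = sorted(set(payload) - top_known)
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {', '.join(unknown)}")

    kwargs: dict = {}
    for key, value in payload.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        elif key == "grid":
            kwargs[key] = ThresholdGrid(tuple(value))
        elif key == "ablation_fractions":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    config = ExperimentConfig(**kwargs)
    log.info("resolved config: %s", config)
    return config


def default_config() -> ExperimentConfig:
    return ExperimentConfig()
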