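"""Run configuration: paths, thresholds, statistics options, seed.

Config files are plain-text YAML with dotted sections mirroring the dataclass
tree, e.g.::

    seed: 7
    alpha: 0.05
    ung_precedence: dr_over_ung
    pipeline:
      quality:
        sharpness_min: 4.1
      dark:
        contrast_min: 12.0
    cohort:
      n_patients: 50
      ung_rate: 0.116

Any key left out keeps its documented default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from retscreen.pipeline import PipelineConfig
from retscreen.synth import CohortSpec


@dataclass
class RunConfig:
    input_dir: Optional[str] = None
    manifest: Optional[str] = None
    output_dir: str = "retscreen_out"
    seed: int = 0
    alpha: float = 0.05
    ung_precedence: str = "dr_over_ung"
    verbosity: int = 1
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def __post_init__(self) -> None:
        if self.ung_precedence not in ("dr_over_ung", "ung_over_dr"):
            raise ValueError("ung_precedence must be 'dr_over_ung' or 'ung_over_dr'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _update_dataclass(obj, values: dict):
    """Recursively overlay a nested dict onto a dataclass tree."""
    for key, val in values.items():
        if not hasattr(obj, key):
            raise ValueError(f"unknown config key: {key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(val, dict):
            _update_dataclass(current, val)
        else:
            setattr(obj, key, val)
    return obj


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides."""
    cfg = RunConfig()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cohort = data.pop("cohort", None)
        _update_dataclass(cfg, data)
        if cohort:
            # CohortSpec validates in __post_init__, so rebuild rather than mutate
            base = dataclasses.asdict(cfg.cohort)
            base.update(cohort)
            base.pop("rater_models", None)
            cfg.cohort = CohortSpec(**base, rater_models=cfg.cohort.rater_models)
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    cfg.__post_init__()
    return cfg
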