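"""Pipeline configuration: one YAML file validated into stage dataclasses.

Unknown keys are rejected so typos never silently fall back to defaults.
A single top-level ``seed`` fans out to per-stage seeds by a fixed
derivation, making any stage individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifier import GlobalModelConfig, ScanRule
from .detector import DetectorConfig, TrainConfig
from .glcm import GlcmConfig
from .synthetic import ForgeryConfig, PhantomConfig
from .windows import AugConfig, GridConfig

_STAGES = {
    "window": GridConfig,
    "augment": AugConfig,
    "detector": DetectorConfig,
    "train": TrainConfig,
    "glcm": GlcmConfig,
    "global": GlobalModelConfig,
    "rule": ScanRule,
    "phantom": PhantomConfig,
    "forgery": ForgeryConfig,
}


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (stable across processes)."""
    import zlib

    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    window: GridConfig = field(default_factory=GridConfig)
    augment: AugConfig = field(default_factory=AugConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    global_cfg: GlobalModelConfig = field(default_factory=GlobalModelConfig)
    rule: ScanRule = field(default_factory=ScanRule)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    forgery: ForgeryConfig = field(default_factory=ForgeryConfig)
    seed: int = 0


def _build(cls, data: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in '{where}' config: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path) -> PipelineConfig:
    """Read and validate a pipeline YAML file (missing sections use defaults)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("pipeline config must be a mapping")
    known = set(_STAGES) | {"seed"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config sections: {sorted(unknown)}")
    kwargs = {}
    for key, cls in _STAGES.items():
        attr = "global_cfg" if key == "global" else key
        section = data.get(key, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section '{key}' must be a mapping")
        kwargs[attr] = _build(cls, section, key)
    return PipelineConfig(seed=int(data.get("seed", 0)), **kwargs)
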