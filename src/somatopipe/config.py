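"""Structured pipeline configuration with strict (unknown-key rejecting)
YAML loading."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimulateConfig:
    n_subjects: int = 20
    n_runs: int = 4
    grid_shape: tuple[int, int, int] = (22, 22, 22)
    voxel_size_mm: float = 1.8
    snr_s1: float = 0.5
    snr_thalamus: float = 0.16
    snr_brainstem: float = 0.05
    pattern_overlap: float = 0.3
    subject_variability: float = 1.0
    amplitude: float = 1.0
    cardiac_amplitude: float = 0.4
    respiratory_amplitude: float = 0.4


@dataclass
class DesignConfig:
    tr_s: float = 2.5
    n_volumes: int = 179
    blocks_per_condition: int = 8
    highpass_s: float = 90.0


@dataclass
class PhysioConfig:
    cardiac_order: int = 4
    resp_order: int = 4
    interaction_order: int = 2
    extras: tuple[str, ...] = ("heart_rate", "rvt")


@dataclass
class GlmConfig:
    smooth_fwhm_mm: float = 2.0
    exclusion_threshold_mm: float = 1.0


@dataclass
class StatsConfig:
    n_perm: int = 5000
    variance_smooth_mm: float = 5.0
    alpha_fwe: float = 0.05
    group_test_condition: str = "face"
    group_test_mask: str = "brainstem"
    rois: tuple[str, ...] = ("left_cuneate", "right_cuneate",
                             "spinal_trigeminal_left",
                             "spinal_trigeminal_right")


@dataclass
class MvpaConfig:
    masks: tuple[str, ...] = ("brainstem", "thalamus", "s1")
    searchlight_mask: str = "brainstem"
    radius_mm: float = 3.0
    n_perm: int = 1000
    n_perm_searchlight: int = 100
    alpha_voxel: float = 0.05
    alpha_cluster: float = 0.05
    run_searchlight: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "somatopipe_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    physio: PhysioConfig = field(default_factory=PhysioConfig)
    glm: GlmConfig = field(default_factory=GlmConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    mvpa: MvpaConfig = field(default_factory=MvpaConfig)


_SECTIONS = {"simulate": SimulateConfig, "design": DesignConfig,
             "physio": PhysioConfig, "glm": GlmConfig,
             "stats": StatsConfig, "mvpa": MvpaConfig}


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown keys in {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if f.type.startswith("tuple") and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed", "out_dir"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for key in ("seed", "out_dir"):
        if key in data:
            kwargs[key] = data[key]
    for section, cls in _SECTIONS.items():
        if section in data:
            if not isinstance(data[section], dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            kwargs[section] = _build(cls, data[section], section)
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def config_to_dict(cfg: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [convert(v) for v in obj]
        return obj
    return convert(cfg)


def save_config(cfg: PipelineConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
    return path
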