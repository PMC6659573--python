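"""Pipeline configuration with protocol defaults and strict YAML loading.

Every default is traceable either to the recording/analysis protocol
(filter band, epoch and baseline windows, rejection thresholds, component
search windows, CSD spline parameters) or to a documented design choice of
this package (EOG blink threshold, onset persistence rule, CSD bypass for
ground-truth recovery runs).  Unknown configuration keys are errors:
silent typos corrupt scientific runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class FilterConfig:
    low_hz: float = 0.3
    high_hz: float = 35.0


@dataclass
class EpochConfig:
    window_ms: tuple = (-500.0, 1000.0)
    baseline_ms: tuple = (-500.0, 0.0)


@dataclass
class RejectionConfig:
    blink_interval_ms: tuple = (-500.0, 200.0)
    blink_threshold_uv: float | None = None     # None -> 4x robust EOG SD
    artifact_interval_ms: tuple = (-500.0, 500.0)
    step_thresh_uv: float = 50.0
    amp_thresh_uv: float = 150.0
    bad_channel_fraction: float = 0.25


@dataclass
class OnsetConfig:
    lowpass_hz: float = 50.0
    smooth_window_ms: float = 25.0
    k_sd: float = 3.0
    min_hold_ms: float = 10.0
    min_onset_ms: float = 100.0


@dataclass
class BehaviorConfig:
    vmrt_range_ms: tuple = (100.0, 500.0)
    outlier_z: float = 3.0
    min_trials: int = 5


@dataclass
class CsdConfig:
    m: int = 4
    legendre_terms: int = 10
    lam: float = 1e-5
    head_radius: float = 1.0
    bypass: bool = False


@dataclass
class PipelineConfig:
    montage: str = "standard-63"
    filter: FilterConfig = field(default_factory=FilterConfig)
    epochs: EpochConfig = field(default_factory=EpochConfig)
    rejection: RejectionConfig = field(default_factory=RejectionConfig)
    onset: OnsetConfig = field(default_factory=OnsetConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    csd: CsdConfig = field(default_factory=CsdConfig)
    seed: int = 0
    mt_roi: str | None = None    # None -> objective per-subject selection

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()

        def tuples_to_lists(obj):
            if isinstance(obj, dict):
                return {k: tuples_to_lists(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return yaml.safe_dump(tuples_to_lists(d), sort_keys=False)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key {path}{key!r}")
        ftype = fields[key].type
        sub = fields[key].default_factory if fields[key].default_factory is not dataclasses.MISSING else None
        if sub is not None and dataclasses.is_dataclass(sub()):
            if not isinstance(value, dict):
                raise ConfigError(f"{path}{key} must be a mapping")
            kwargs[key] = _build(type(sub()), value, f"{path}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path_or_dict) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file path or a dict."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return _build(PipelineConfig, data, "")
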