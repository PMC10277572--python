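"""Structured run configuration: one source of truth for a pipeline run.

A :class:`RunConfig` gathers every tunable of the nine-model pipeline in
per-stage sections, round-trips through YAML unchanged, and converts to
the in-memory configs the library modules take.  CLI flags override the
file's values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .features_hc import HCConfig
from .fusion_select import STRATEGIES
from .modeling import NineModelConfig
from .partition import DEFAULT_INTERVALS, ShellSpec
from .polar import DEFAULT_HU_WINDOW

__all__ = ["RunConfig"]


def _to_tuples(seq):
    return tuple(tuple(x) if isinstance(x, (list, tuple)) else x for x in seq)


@dataclass
class RunConfig:
    # paths
    cohort_dir: str | None = None
    out_dir: str | None = None
    # partition
    shell_intervals: tuple = DEFAULT_INTERVALS
    # polar
    angle_step: float = 10.0
    slice_size: tuple = (224, 224)
    hu_window: tuple = DEFAULT_HU_WINDOW
    # handcrafted features
    hc_bin_width: float = 25.0
    hc_filters: tuple = HCConfig().filters
    hc_log_sigmas: tuple = HCConfig().log_sigmas
    hc_classes: tuple = HCConfig().classes
    hc_shape: bool = True
    # deep features
    backbone_seed: int = 0
    backbone_channels: tuple = (16, 32, 64, 128, 256)
    # modeling
    strategies: tuple = STRATEGIES
    split_ratio: float = 0.2
    folds: int = 10
    seed: int = 0
    fill: float = -1024.0

    def __post_init__(self) -> None:
        self.shell_intervals = _to_tuples(self.shell_intervals)
        for name in ("slice_size", "hu_window", "hc_filters", "hc_log_sigmas",
                     "hc_classes", "backbone_channels", "strategies"):
            setattr(self, name, tuple(getattr(self, name)))

    # -- conversions -------------------------------------------------
    def hc_config(self) -> HCConfig:
        return HCConfig(
            bin_width=self.hc_bin_width,
            filters=self.hc_filters,
            log_sigmas=self.hc_log_sigmas,
            classes=self.hc_classes,
            shape=self.hc_shape,
        )

    def nine_model_config(self) -> NineModelConfig:
        return NineModelConfig(
            shells=ShellSpec(self.shell_intervals),
            hc_config=self.hc_config(),
            angle_step=self.angle_step,
            slice_size=self.slice_size,
            hu_window=self.hu_window,
            backbone_seed=self.backbone_seed,
            backbone_channels=self.backbone_channels,
            split_ratio=self.split_ratio,
            folds=self.folds,
            seed=self.seed,
            fill=self.fill,
        )

    # -- serialization -----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        payload = self.to_dict()
        # YAML has no tuple type; store sequences as lists.
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(payload), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _listify(obj):
    if isinstance(obj, (list, tuple)):
        return [_listify(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj
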