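"""Run configuration: per-channel segmentation parameters and cascade cutoffs.

A single YAML file configures a whole run; unknown keys are rejected so that
typos fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .image_io import DEFAULT_TOKEN_MAP
from .segmentation import DEFAULT_MAX_ECCENTRICITY, SegmentationParams


def _bec_params() -> SegmentationParams:
    return SegmentationParams(
        threshold_floor=50.0, smoothing_sigma=1.0,
        min_diameter=26.0, max_diameter=130.0, fill_holes=True,
    )


def _tcell_params() -> SegmentationParams:
    return SegmentationParams(
        threshold_floor=60.0, smoothing_sigma=1.0,
        min_diameter=7.0, max_diameter=40.0, fill_holes=True,
    )


def _membrane_params() -> SegmentationParams:
    return SegmentationParams(
        threshold_floor=60.0, smoothing_sigma=0.5,
        min_diameter=3.0, max_diameter=60.0,
    )


def _lysosome_params() -> SegmentationParams:
    return SegmentationParams(
        threshold_floor=60.0, smoothing_sigma=0.5,
        min_diameter=2.0, max_diameter=14.0,
    )


@dataclass
class PipelineConfig:
    """All tunables of the detection cascade.

    * ``membrane_overlap_fraction`` — a T cell counts as membrane-positive
      when detected membrane-label objects cover at least this fraction of
      its footprint (surface cells carry a bright rim; enclosed cells are
      shielded from the label).
    * ``cytoplasm_overlap_cutoff`` — a membrane-negative on-BEC T cell is
      cytoplasm-displacing (hence internalized) when *less* than this
      fraction of its footprint carries above-threshold BEC signal.
    * ``max_eccentricity`` — remnant filter applied after masking steps;
      partially clipped cells are elongated and exceed it.
    """

    token_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TOKEN_MAP))
    bec: SegmentationParams = field(default_factory=_bec_params)
    tcell: SegmentationParams = field(default_factory=_tcell_params)
    membrane: SegmentationParams = field(default_factory=_membrane_params)
    lysosome: SegmentationParams = field(default_factory=_lysosome_params)
    membrane_min_area_px: int = 10
    membrane_overlap_fraction: float = 0.05
    cytoplasm_overlap_cutoff: float = 0.5
    max_eccentricity: float = DEFAULT_MAX_ECCENTRICITY
    pixel_size: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.membrane_overlap_fraction <= 1:
            raise ConfigError("membrane_overlap_fraction must lie in [0, 1]")
        if not 0 < self.cytoplasm_overlap_cutoff <= 1:
            raise ConfigError("cytoplasm_overlap_cutoff must lie in (0, 1]")
        if not 0 <= self.max_eccentricity <= 1:
            raise ConfigError("max_eccentricity must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")

    # -- (de)serialisation --------------------------------------------------
    _SEG_ROLES = ("bec", "tcell", "membrane", "lysosome")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {unknown}")
        seg_names = {f.name for f in dataclasses.fields(SegmentationParams)}
        for role in cls._SEG_ROLES:
            if role in data and isinstance(data[role], dict):
                bad = sorted(set(data[role]) - seg_names)
                if bad:
                    raise ConfigError(f"unknown key(s) under {role!r}: {bad}")
                base = dataclasses.asdict(getattr(cls(), role))
                base.update(data[role])
                try:
                    data[role] = SegmentationParams(**base)
                except ValueError as exc:
                    raise ConfigError(f"invalid {role} parameters: {exc}") from exc
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"configuration file {path} is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
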