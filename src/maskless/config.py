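"""Run configuration: a single YAML document driving the whole pipeline.

Unknown keys are rejected; every run writes a manifest echoing the fully
resolved configuration (defaults filled in) plus the master seed, so a run
is reproducible from its manifest alone.  All coordinates in files are
0-based, intervals half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .design import DesignSpec
from .layout import DmdGeometry
from .photochem import (DEFAULT_GLOBAL_SCATTER, PhotochemParams,
                        calibrate_photolysis_rate)
from .simulate import ChemParams


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class LayoutConfig:
    design: str = "2SZ"
    rows: int = 768
    cols: int = 1024
    n_features: int | None = None
    mirror_pitch_um: float = 14.0
    mirror_gap_um: float = 1.0

    def geometry(self) -> DmdGeometry:
        return DmdGeometry(rows=self.rows, cols=self.cols,
                           mirror_pitch_um=self.mirror_pitch_um,
                           mirror_gap_um=self.mirror_gap_um)


@dataclass(frozen=True)
class PhotoConfig:
    """Photochemistry block; k_rate is derived from (yield, exposure)."""

    photolysis_yield: float = 0.95
    nominal_exposure: float = 3.0
    global_scatter_coeff: float = DEFAULT_GLOBAL_SCATTER
    side_leak: float = 0.005
    corner_leak: float = 0.0005
    edge_falloff_amplitude: float = 0.1
    edge_falloff_exponent: float = 4.0
    reflection_enabled: bool = False
    reflection_extra_dose: float = 0.0
    reflection_region: list[int] | None = None
    reflection_onset_fraction: float = 0.0

    def params(self) -> PhotochemParams:
        return PhotochemParams(
            k_rate=calibrate_photolysis_rate(self.photolysis_yield,
                                             self.nominal_exposure),
            nominal_exposure=self.nominal_exposure,
            global_scatter_coeff=self.global_scatter_coeff,
            side_leak=self.side_leak, corner_leak=self.corner_leak,
            edge_falloff_amplitude=self.edge_falloff_amplitude,
            edge_falloff_exponent=self.edge_falloff_exponent,
            reflection_enabled=self.reflection_enabled,
            reflection_extra_dose=self.reflection_extra_dose,
            reflection_region=(tuple(self.reflection_region)
                               if self.reflection_region else None),
            reflection_onset_fraction=self.reflection_onset_fraction)


@dataclass(frozen=True)
class ChemConfig:
    coupling_efficiency: dict[str, float] = field(
        default_factory=lambda: {"A": 0.9995, "C": 0.9995, "G": 0.997,
                                 "T": 0.9995})
    capping_enabled: bool = False
    capping_efficiency: float = 0.999
    baseline_substitution_rate: float = 0.0005
    block_rate: float = 0.0
    molecules_per_feature: int = 100

    def params(self, seed: int) -> ChemParams:
        return ChemParams(
            coupling_efficiency=dict(self.coupling_efficiency),
            capping_enabled=self.capping_enabled,
            capping_efficiency=self.capping_efficiency,
            baseline_substitution_rate=self.baseline_substitution_rate,
            block_rate=self.block_rate,
            molecules_per_feature=self.molecules_per_feature,
            seed=seed)


@dataclass(frozen=True)
class AnalysisConfig:
    min_identity: float = 0.5
    min_reads: int = 5
    n_areas: int = 4


@dataclass(frozen=True)
class DesignConfig:
    n_oligos: int = 500
    oligo_len: int = 67
    k: int = 5
    min_oligo_coverage: int = 2
    max_homopolymer: int = 3
    fixed_5p: str = ""
    fixed_3p: str = ""

    def spec(self, seed: int) -> DesignSpec:
        return DesignSpec(n_oligos=self.n_oligos, oligo_len=self.oligo_len,
                          k=self.k,
                          min_oligo_coverage=self.min_oligo_coverage,
                          max_homopolymer=self.max_homopolymer,
                          fixed_5p=self.fixed_5p, fixed_3p=self.fixed_3p,
                          seed=seed)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    write_masks: bool = True
    design: DesignConfig = field(default_factory=DesignConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    photochem: PhotoConfig = field(default_factory=PhotoConfig)
    chem: ChemConfig = field(default_factory=ChemConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        blocks = {
            "design": DesignConfig, "layout": LayoutConfig,
            "photochem": PhotoConfig, "chem": ChemConfig,
            "analysis": AnalysisConfig,
        }
        kwargs: dict = {}
        for key, val in data.items():
            if key in blocks:
                if not isinstance(val, dict):
                    raise ConfigError(f"{key} block must be a mapping")
                kwargs[key] = _from_mapping(blocks[key], val, key)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))
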