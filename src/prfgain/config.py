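"""Pipeline configuration: typed sections with lossless TOML round-trip."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "StimulusConfig",
    "SimulationConfig",
    "FittingConfig",
    "ModelConfig",
    "StatsConfig",
    "PipelineConfig",
]


@dataclass
class StimulusConfig:
    n_passes_per_direction: int = 3
    n_positions_per_pass: int = 24
    step_dva: float = 0.34
    dwell_s: float = 1.6
    pause_s: float = 4.8
    n_blanks: int = 4
    blank_duration_s: float = 38.4
    aperture_radius_dva: float = 3.6
    bar_width_dva: float = 0.9
    extent_dva: float = 7.2
    grid_coarse: int = 31
    grid_fine: int = 101
    order_seed: int = 0


@dataclass
class SimulationConfig:
    n_voxels: int = 100
    ecc_lo: float = 0.2
    ecc_hi: float = 3.3
    size_intercept: float = 0.4
    size_slope: float = 0.25
    size_jitter_sd: float = 0.05
    amplitude: float = 5.0
    baseline: float = 100.0
    noise_sd: float = 1.0  # 20% of amplitude
    sigma_fix: float = 2.0
    sigma_stim_color: float = 0.95
    sigma_stim_tf: float = 1.05
    meridian_bias: float = 0.0
    seed: int = 0


@dataclass
class FittingConfig:
    ridge_lambda: float = 1e6
    xtol: float = 1e-4
    maxiter: int = 300
    xy_bound: float = 5.0
    sigma_lo: float = 0.05
    sigma_hi: float = 10.0
    ecc_max: float = 3.3
    size_max: float = 7.2
    r2_min: float = 0.1


@dataclass
class ModelConfig:
    sigma_fix_lo: float = 1.5
    sigma_fix_hi: float = 2.5
    sigma_stim_lo: float = 0.6
    sigma_stim_hi: float = 1.6
    grid_n_per_dim: int = 50
    n_bins_per_dim: int = 8


@dataclass
class StatsConfig:
    n_boot: int = 10_000
    mad_k: float = 5.0
    alpha: float = 0.05
    seed: int = 0


@dataclass
class PipelineConfig:
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    _SECTIONS = {
        "stimulus": StimulusConfig,
        "simulation": SimulationConfig,
        "fitting": FittingConfig,
        "model": ModelConfig,
        "stats": StatsConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            known = {f.name for f in dataclasses.fields(section_cls)}
            payload = d.get(name, {})
            unknown = set(payload) - known
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            kwargs[name] = section_cls(**payload)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name)) for name in self._SECTIONS}

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path) -> None:
        Path(path).write_text(self.to_toml_str())

    def to_toml_str(self) -> str:
        lines = []
        for name in self._SECTIONS:
            lines.append(f"[{name}]")
            for key, val in dataclasses.asdict(getattr(self, name)).items():
                if isinstance(val, bool):
                    lines.append(f"{key} = {'true' if val else 'false'}")
                elif isinstance(val, str):
                    lines.append(f'{key} = "{val}"')
                else:
                    lines.append(f"{key} = {val!r}")
            lines.append("")
        return "\n".join(lines)
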