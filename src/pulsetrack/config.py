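"""Pipeline configuration.

Flat dataclasses with the published defaults (canceller: M=21, μ=1e-4;
tracker: L=5, β=0.95, μ_a=0.025; feedback band-pass: β_hr=0.8), loadable
from nested YAML/JSON mappings::

    preprocessing: {fs_raw: 125, fs_target: 25, band_low_hz: 0.4,
                    band_high_hz: 4.0, ppg_combine: mean}
    ma:  {algorithm: sign_sign, taps: 21, mu: 0.0001}
    anf: {variant: nr_osc, L: 5, beta: 0.95, mu_a: 0.025,
          beta_hr: 0.8, f_init_bpm: 90, feedback: true}
    window: {window_s: 8.0, step_s: 2.0, stat: mean}
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["PreprocessingConfig", "MAConfig", "ANFConfig", "WindowConfig",
           "PipelineConfig", "load_config"]


@dataclass
class PreprocessingConfig:
    fs_raw: float = 125.0
    fs_target: float = 25.0
    band_low_hz: float = 0.4
    band_high_hz: float = 4.0
    ppg_combine: str = "mean"


@dataclass
class MAConfig:
    algorithm: str = "sign_sign"   # sign_sign | nlms | none
    taps: int = 21
    mu: float = 1e-4
    eps: float = 1e-8              # NLMS normalization regularizer

    def __post_init__(self):
        if self.algorithm not in ("sign_sign", "nlms", "none"):
            raise ValueError(f"unknown MA algorithm {self.algorithm!r}")
        if self.taps < 1:
            raise ValueError(f"ma.taps must be >= 1, got {self.taps}")
        if not 0.0 < self.mu <= 1.0:
            raise ValueError(f"ma.mu must be in (0, 1], got {self.mu}")


@dataclass
class ANFConfig:
    variant: str = "nr_osc"        # osc | nr_osc
    L: int = 5
    beta: float = 0.95
    mu_a: float = 0.025
    beta_hr: float = 0.8
    f_init_bpm: float = 90.0
    feedback: bool = True

    def __post_init__(self):
        if self.variant not in ("osc", "nr_osc"):
            raise ValueError(f"unknown ANF variant {self.variant!r}")
        if self.L < 1:
            raise ValueError(f"anf.L must be >= 1, got {self.L}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"anf.beta must be in (0, 1), got {self.beta}")
        if not 0.0 < self.beta_hr < 1.0:
            raise ValueError(f"anf.beta_hr must be in (0, 1), got {self.beta_hr}")


@dataclass
class WindowConfig:
    window_s: float = 8.0
    step_s: float = 2.0
    stat: str = "mean"             # mean | median

    def __post_init__(self):
        if not self.window_s >= self.step_s > 0:
            raise ValueError(
                f"need window_s >= step_s > 0, got window_s={self.window_s}, "
                f"step_s={self.step_s}")
        if self.stat not in ("mean", "median"):
            raise ValueError(f"window stat must be 'mean' or 'median', got {self.stat!r}")


@dataclass
class PipelineConfig:
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    ma: MAConfig = field(default_factory=MAConfig)
    anf: ANFConfig = field(default_factory=ANFConfig)
    window: WindowConfig = field(default_factory=WindowConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        return cls(
            preprocessing=PreprocessingConfig(**data.get("preprocessing", {})),
            ma=MAConfig(**data.get("ma", {})),
            anf=ANFConfig(**data.get("anf", {})),
            window=WindowConfig(**data.get("window", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a config file if given, then apply section overrides."""
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    if overrides:
        data = cfg.to_dict()
        for section, values in overrides.items():
            if section not in data:
                raise ValueError(f"unknown config section {section!r}")
            data[section].update(values)
        cfg = PipelineConfig.from_dict(data)
    return cfg
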