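"""Pipeline configuration: defaults, presets and YAML round-tripping.

All numeric defaults are the working values of the segmentation framework:
the Gaussian-derivative bandpass scales (one triplet for small structures,
one for large — exposed as gestational-age presets), the feature-asymmetry
noise threshold and regulariser, the affinity weights and trained object
phase statistics, the connectivity threshold, the c-scale flatness threshold
and the curvature-flow budget.  Unknown keys in a config file are rejected
rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from . import completion as _completion
from . import features as _features
from . import fuzzyconn as _fuzzyconn

__all__ = ["PipelineConfig", "load_config", "save_config", "PRESETS"]


@dataclass(frozen=True)
class PhaseConfig:
    sigma: float = 27.0
    convention: str = "folded"  # folded | raw
    padding: str = "mirror"  # mirror | wrap

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("phase.sigma must be > 0")
        if self.convention not in ("folded", "raw"):
            raise ValueError("phase.convention must be 'folded' or 'raw'")
        if self.padding not in ("mirror", "wrap"):
            raise ValueError("phase.padding must be 'mirror' or 'wrap'")


@dataclass(frozen=True)
class FAConfig:
    scales: tuple[float, ...] = _features.SCALES_UNDER30
    Ts: float = _features.DEFAULT_TS
    epsilon: float = _features.DEFAULT_EPSILON
    nms_directions: int = 8

    def __post_init__(self) -> None:
        if len(self.scales) < 1 or any(s <= 0 for s in self.scales):
            raise ValueError("fa.scales must be a non-empty list of positive scales")
        if self.Ts < 0:
            raise ValueError("fa.Ts must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("fa.epsilon must be > 0")
        if self.nms_directions < 1:
            raise ValueError("fa.nms_directions must be >= 1")


@dataclass(frozen=True)
class FCConfig:
    omega1: float = _fuzzyconn.DEFAULT_OMEGA1
    omega2: float = _fuzzyconn.DEFAULT_OMEGA2
    m_o: float = _fuzzyconn.DEFAULT_M_O
    sigma_o: float = _fuzzyconn.DEFAULT_SIGMA_O
    T_FC: float = _fuzzyconn.DEFAULT_T_FC
    pair_edge: str = "max"
    train_on_roi: bool = False  # refit m_o/sigma_o from a supplied ROI

    def __post_init__(self) -> None:
        # delegate range checks to the affinity parameter object
        _fuzzyconn.AffinityParams(
            omega1=self.omega1,
            omega2=self.omega2,
            m_o=self.m_o,
            sigma_o=self.sigma_o,
            pair_edge=self.pair_edge,
        )
        if not 0.0 <= self.T_FC <= 1.0:
            raise ValueError("fc.T_FC must be in [0, 1]")


@dataclass(frozen=True)
class CompletionConfig:
    t: float = _completion.DEFAULT_T
    D: int = _completion.DEFAULT_D
    min_gap_length: int = _completion.DEFAULT_MIN_GAP
    contact_tol: float = _completion.DEFAULT_CONTACT_TOL

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("completion.t must be > 0")
        if self.D < 1:
            raise ValueError("completion.D must be >= 1")
        if self.min_gap_length < 1:
            raise ValueError("completion.min_gap_length must be >= 1")
        if self.contact_tol < 0:
            raise ValueError("completion.contact_tol must be >= 0")


@dataclass(frozen=True)
class MCFConfig:
    n_iter: int = 25
    dt: float = 0.2

    def __post_init__(self) -> None:
        if self.n_iter < 0:
            raise ValueError("mcf.n_iter must be >= 0")
        if not 0 < self.dt <= 0.25:
            raise ValueError("mcf.dt must be in (0, 0.25]")


@dataclass(frozen=True)
class QualityConfig:
    levels: int = 256

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("quality.levels must be >= 2")


_SECTIONS = {
    "phase": PhaseConfig,
    "fa": FAConfig,
    "fc": FCConfig,
    "completion": CompletionConfig,
    "mcf": MCFConfig,
    "quality": QualityConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Full parameter set of the segmentation pipeline."""

    phase: PhaseConfig = field(default_factory=PhaseConfig)
    fa: FAConfig = field(default_factory=FAConfig)
    fc: FCConfig = field(default_factory=FCConfig)
    completion: CompletionConfig = field(default_factory=CompletionConfig)
    mcf: MCFConfig = field(default_factory=MCFConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["fa"]["scales"] = list(self.fa.scales)
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section_data = dict(data.get(name, {}))
            valid = {f.name for f in fields(section_cls)}
            bad = set(section_data) - valid
            if bad:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(bad)}")
            if name == "fa" and "scales" in section_data:
                section_data["scales"] = tuple(float(s) for s in section_data["scales"])
            kwargs[name] = section_cls(**section_data)
        return cls(**kwargs)


#: gestational-age presets: filter scales for small vs large arm structures
PRESETS = {
    "under30": PipelineConfig(
        phase=PhaseConfig(sigma=27.0),
        fa=FAConfig(scales=_features.SCALES_UNDER30),
    ),
    "over30": PipelineConfig(
        phase=PhaseConfig(sigma=35.0),
        fa=FAConfig(scales=_features.SCALES_OVER30),
    ),
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a configuration to YAML; load(save(c)) == c."""
    with open(path, "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=True)
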