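"""Run configuration: every tunable of the pipeline in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .binding import DEFAULT_CONTACT_CUTOFF, DEFAULT_MIN_FREQUENCY
from .ensemble import EnsembleFilterConfig, MembershipThresholds
from .gnm import DEFAULT_CUTOFF, DEFAULT_K_MAX, DEFAULT_SIGMA_MIN
from .hinges import HingeFilterParams


@dataclass
class GnmConfig:
    cutoff: float = DEFAULT_CUTOFF
    sigma_min: float = DEFAULT_SIGMA_MIN
    k_max: int = DEFAULT_K_MAX


@dataclass
class BindingConfig:
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    min_frequency: float = DEFAULT_MIN_FREQUENCY


@dataclass
class RunConfig:
    gnm: GnmConfig = field(default_factory=GnmConfig)
    hinge: HingeFilterParams = field(default_factory=HingeFilterParams)
    binding: BindingConfig = field(default_factory=BindingConfig)
    ensemble: EnsembleFilterConfig = field(default_factory=EnsembleFilterConfig)
    ensemble_profile: str | None = None     # "small" | "large" | None (auto)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        if "gnm" in d:
            cfg.gnm = GnmConfig(**d["gnm"])
        if "hinge" in d:
            cfg.hinge = HingeFilterParams(**d["hinge"])
        if "binding" in d:
            cfg.binding = BindingConfig(**d["binding"])
        if "ensemble" in d:
            e = d["ensemble"]
            cfg.ensemble = EnsembleFilterConfig(
                small=MembershipThresholds(**e.get("small", {})),
                large=MembershipThresholds(**e.get("large", {})),
                size_boundary=e.get("size_boundary", 550),
            )
        cfg.ensemble_profile = d.get("ensemble_profile")
        cfg.seed = d.get("seed", 0)
        return cfg

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
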