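"""Run configuration: YAML-backed, schema-checked."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig", "ConfigError"]

_KNOWN_STAGES = {
    "simulate-pillars", "simulate-curve", "simulate-blobs",
    "simulate-fibers", "simulate-groups",
    "track-pillars", "fit-afm", "quantify-blobs", "coherency", "coloc",
    "stats-ttest", "stats-anova2", "stats-ddct",
}

# stages whose parameters require a physical pixel size
_NEEDS_PIXEL_SIZE = {"track-pillars", "quantify-blobs"}


class ConfigError(ValueError):
    """Raised for schema-invalid run configurations; lists offending keys."""


@dataclass
class RunConfig:
    stage: str
    out_dir: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    pixel_size_um: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        problems = []
        if self.stage not in _KNOWN_STAGES:
            problems.append(
                f"stage: unknown stage {self.stage!r} "
                f"(known: {sorted(_KNOWN_STAGES)})")
        if self.stage in _NEEDS_PIXEL_SIZE and not self.pixel_size_um:
            problems.append("pixel_size_um: required for stage "
                            f"{self.stage!r}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            problems.append("pixel_size_um: must be > 0")
        if self.log_level not in ("DEBUG", "INFO", "WARN", "WARNING", "ERROR"):
            problems.append(f"log_level: unknown level {self.log_level!r}")
        if not isinstance(self.seed, int):
            problems.append("seed: must be an integer")
        if self.stage == "track-pillars" and \
                float(self.params.get("stiffness_nn_per_um", 0)) <= 0:
            problems.append("params.stiffness_nn_per_um: required and > 0")
        if problems:
            raise ConfigError("invalid config: " + "; ".join(problems))
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"invalid config: unknown key(s) "
                              f"{sorted(unknown)}")
        missing = {"stage", "out_dir"} - set(data)
        if missing:
            raise ConfigError(f"invalid config: missing key(s) "
                              f"{sorted(missing)}")
        return cls(**data).validate()
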