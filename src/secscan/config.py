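"""Run configuration: bundled/ad-hoc models, thresholds, output options."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from secscan.cmcore import BUNDLED, CovarianceModel, load_bundled_model


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    models: list[str] = field(default_factory=lambda: ["eukaryota", "bacteria", "archaea"])
    threshold: float = 40.0
    stringent_threshold: float = 55.0
    plot: bool = False
    outdir: str = "."
    log_level: str = "INFO"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.stringent_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if self.threshold > self.stringent_threshold:
            raise ConfigError("threshold must not exceed the stringent threshold")

    def load_models(self) -> list[CovarianceModel]:
        out = []
        for name in self.models:
            if name in BUNDLED:
                out.append(load_bundled_model(name))
            else:
                path = Path(name)
                if not path.exists():
                    raise ConfigError(f"model {name!r}: not bundled and not a file")
                out.append(CovarianceModel.from_json(path.read_text()))
        return out

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)
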