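"""Run configuration: the analysis knobs, their defaults, and TOML loading.

Flags always win over the config file; the fully resolved configuration is
echoed into every report header so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .core import ValidationError


@dataclass
class RunConfig:
    similarity_min_score: int = 1
    linker_medium_from: float = 60.0  # percent; below this is SHORT
    linker_long_from: float = 100.0  # at or above this is LONG
    linker_observed_max: float = 160.0
    filter_gap_tolerance: float = 0.0
    filter_treat_x_as_gap: bool = True
    synteny_min_block_size: int = 3
    synteny_max_gap: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.linker_medium_from < self.linker_long_from:
            raise ValidationError("linker thresholds must be strictly increasing")
        if not 0.0 <= self.filter_gap_tolerance <= 1.0:
            raise ValidationError("gap tolerance must lie in [0,1]")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def replace(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    def as_header_lines(self, version: str) -> list:
        lines = [f"# tertkit {version}"]
        for f in dataclasses.fields(self):
            lines.append(f"# config {f.name} = {getattr(self, f.name)}")
        return lines
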