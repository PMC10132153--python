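"""Run configuration shared by the pipeline stages and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .calls import EquivalenceParams
from .errors import ConfigError


@dataclass
class RunConfig:
    """Tunable parameters of a full classification + sequence-analysis run."""

    alpha: float = 0.05
    q: float = 0.05
    gate: str = "raw"
    equivalence: EquivalenceParams = field(default_factory=EquivalenceParams)
    pseudocount: float = 0.5
    w_min: int = 10
    w_max: int = 25
    scan_p_threshold: float = 1e-4
    uorf_mode: str = "atg_only"
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.q < 1:
            raise ConfigError("q must be in (0, 1)")
        if self.gate not in ("raw", "bh"):
            raise ConfigError("gate must be 'raw' or 'bh'")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if not 1 <= self.w_min <= self.w_max:
            raise ConfigError("require 1 <= w_min <= w_max")
        if not 0 < self.scan_p_threshold <= 1:
            raise ConfigError("scan_p_threshold must be in (0, 1]")
        if self.uorf_mode not in ("atg_only", "atg_plus_alternatives"):
            raise ConfigError("uorf_mode must be atg_only or atg_plus_alternatives")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        eq = raw.pop("equivalence", None)
        cfg = cls(**raw)
        if eq:
            cfg.equivalence = EquivalenceParams(**eq)
        return cfg
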