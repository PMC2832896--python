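"""Run configuration: validated defaults for every tunable in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import InvalidConfigError
from .ga import GASettings

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables of a run; defaults reproduce the canonical study settings.

    hill_n = 4 (tetrameric TF), tau_max = 2.5 h, W_MAX = (5, 5, 5, 2) for
    (c, k, K, d), unit activity box, 10 restarts, top fraction 0.15, 3 grid
    insertions (7 -> 25 points), RK4 step 0.05 h.
    """

    ga: GASettings = field(default_factory=GASettings)
    step: float = 0.05
    w_max: tuple = (5.0, 5.0, 5.0, 2.0)
    tau_max: float = 2.5
    hill_n: int = 4
    sites_m: int = 1
    expand_inserts: int = 3
    top_fraction: float = 0.15
    k_min: float = 0.05
    restarts: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.ga, dict):
            self.ga = GASettings(**self.ga)
        self.ga.validate()
        self.w_max = tuple(float(w) for w in self.w_max)
        if self.step <= 0:
            raise InvalidConfigError("step must be > 0")
        if len(self.w_max) != 4 or any(w <= 0 for w in self.w_max):
            raise InvalidConfigError("w_max must be four positive widths for (c, k, K, d)")
        if self.tau_max < 0:
            raise InvalidConfigError("tau_max must be >= 0")
        if self.hill_n < 1 or self.sites_m < 1:
            raise InvalidConfigError("hill_n and sites_m must be >= 1")
        if self.expand_inserts < 0:
            raise InvalidConfigError("expand_inserts must be >= 0")
        if not 0 < self.top_fraction <= 1:
            raise InvalidConfigError("top_fraction must lie in (0, 1]")
        if self.k_min < 0:
            raise InvalidConfigError("k_min must be >= 0")
        if self.restarts < 1:
            raise InvalidConfigError("restarts must be >= 1")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise InvalidConfigError("log_level must be DEBUG/INFO/WARNING/ERROR")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise InvalidConfigError("config file must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise InvalidConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["w_max"] = list(self.w_max)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
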