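"""Run-level configuration shared by the library and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .em import EMConfig


@dataclass
class RunConfig:
    """Thresholds and numerics for a calling run.

    ``call_threshold`` is the minimum posterior for assigning a dosage;
    ``peak_threshold`` the maximum fraction of called samples permitted
    in a single dosage class; ``extreme_trigger``/``adjacent_trigger``
    drive the re-evaluation of thinly fitted extreme components.
    """

    call_threshold: float = 0.75
    peak_threshold: float = 0.9
    na_fraction_max: float = 0.25
    extreme_trigger: float = 0.025
    adjacent_trigger: float = 0.15
    em_tol: float = 1e-6
    em_max_iter: int = 500
    var_floor: float = 1e-6
    min_samples: int = 10
    seed: int = 1
    plot: bool = False
    threads: int = 1

    def __post_init__(self):
        for name in ("call_threshold", "peak_threshold", "na_fraction_max",
                     "extreme_trigger", "adjacent_trigger"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")

    def em_config(self) -> EMConfig:
        return EMConfig(tol=self.em_tol, max_iter=self.em_max_iter,
                        var_floor=self.var_floor,
                        min_samples=self.min_samples)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML mapping; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
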