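"""Run configuration: YAML-backed, validated, fully resolvable to a run.

A config has up to four blocks::

    params:       # ModelParams fields
      t0: 1000
      N: 1000
      n_star: 5
    environment:  # exactly one of: abundances / tsv / generate
      abundances: [0.2, 0.8]
      # tsv: path/to/env.tsv
      # generate: {n_antigens: 100, log10_range: [-6, -2], distribution: log-uniform}
    scenario:     # montecarlo only
      name: infection
      p: 0.05
      n_reps: 100000
    seed: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .environment import AntigenEnvironment, make_environment, read_environment_tsv
from .generate import generate_environment
from .params import ModelParams

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    """Raised for structurally invalid run configurations."""


@dataclass
class RunConfig:
    params: ModelParams
    environment_spec: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed must be a nonnegative integer, got {self.seed!r}")
        sources = [k for k in ("abundances", "tsv", "generate") if k in self.environment_spec]
        if len(sources) > 1:
            raise ConfigError(f"environment block must name one source, got {sources}")
        if "tsv" in self.environment_spec:
            path = Path(self.environment_spec["tsv"])
            if not path.exists():
                raise ConfigError(f"environment TSV does not exist: {path}")

    def resolve_environment(self, rng: np.random.Generator | None = None) -> AntigenEnvironment:
        spec = self.environment_spec
        if "abundances" in spec:
            return make_environment(
                spec["abundances"], spec.get("ids"), spec.get("categories")
            )
        if "tsv" in spec:
            return read_environment_tsv(spec["tsv"])
        if "generate" in spec:
            g = dict(spec["generate"])
            if rng is None:
                rng = np.random.default_rng(self.seed)
            if "log10_range" in g:
                g["log10_range"] = tuple(g["log10_range"])
            return generate_environment(rng=rng, **g)
        raise ConfigError("config has no environment block")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "environment": self.environment_spec,
            "scenario": self.scenario,
            "seed": self.seed,
        }


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - {"params", "environment", "scenario", "seed"}
    if unknown:
        raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
    try:
        params = ModelParams(**(raw.get("params") or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid params block: {exc}") from exc
    return RunConfig(
        params=params,
        environment_spec=raw.get("environment") or {},
        scenario=raw.get("scenario") or {},
        seed=raw.get("seed", 0),
    )
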