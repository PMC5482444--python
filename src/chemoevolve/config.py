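"""Run configuration: validated, serializable, reproducible.

A run is fully determined by its RunConfig plus seed.  Unknown keys are
rejected by name; defaults follow the model's standard setting (world
length 100, speed 1, field update interval T/100, agent step
min(T, L/v, tau/20), Metropolis temperature 0.005, 600-generation
convergence window).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .evolve import EvolutionConfig, desk_config
from .response import ResponseParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    T: float = 1000.0
    L: float = 50.0
    ell: float = 100.0
    v: float = 1.0
    seed: int = 0
    strategy: str | None = None
    # explicit response parameters (optional; evolution initializes its own)
    alpha0: float | None = None
    beta: float | None = None
    A: float | None = None
    B: float | None = None
    tau: float | None = None
    # evolution settings
    U: float = 0.005
    r_range: float = 0.2
    n_replicates: int = 10
    stop_factor: float = 50.0
    t_max_factor: float = 1e4
    window: int = 600
    max_generations: int = 100_000
    scale: str = "full"  # full | desk

    def __post_init__(self) -> None:
        if self.scale not in ("full", "desk"):
            raise ValueError(f"scale must be 'full' or 'desk', got {self.scale!r}")

    @property
    def dt_c(self) -> float:
        return self.T / 100.0

    @property
    def dt_b(self) -> float:
        cands = [self.T, self.L / self.v]
        if self.tau is not None:
            cands.append(self.tau / 20.0)
        return min(cands)

    def response_params(self) -> ResponseParams:
        missing = [k for k in ("alpha0", "beta", "A", "B", "tau") if getattr(self, k) is None]
        if missing:
            raise ValueError(f"response parameters not set: {', '.join(missing)}")
        return ResponseParams(
            alpha0=self.alpha0, beta=self.beta, A=self.A, B=self.B, tau=self.tau,
            strategy=self.strategy or "speculator",
        )

    def evolution_config(self) -> EvolutionConfig:
        if self.strategy is None:
            raise ValueError("evolution requires a strategy")
        common = dict(
            seed=self.seed, U=self.U, r_range=self.r_range, window=self.window,
            v=self.v, ell=self.ell,
        )
        if self.scale == "desk":
            return desk_config(
                self.strategy, self.T, self.L,
                max_generations=min(self.max_generations, 3000), **common,
            )
        return EvolutionConfig(
            strategy=self.strategy, T=self.T, L=self.L,
            n_replicates=self.n_replicates, stop_factor=self.stop_factor,
            t_max_factor=self.t_max_factor, max_generations=self.max_generations,
            **common,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config, filling defaults and rejecting unknown keys."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
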