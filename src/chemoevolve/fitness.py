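"""Fitness of a chemotactic response in stochastic attractant fields.

Fitness approximates the average cell-division rate as the inverse of the
time D a bacterium needs to experience a fixed amount of attractant
(``stop_factor * T`` units, 50T at full scale):

    F = T * <1/D_i>_i

averaged over replicate field realizations.  Wild-type and mutant are
evaluated on the *same* field seeds (common random fields) so that lucky
environments do not masquerade as good genotypes; agent-level randomness
is fresh per run.  Relative fitness divides by the fitness of a
non-chemotaxing baseline -- an always-running agent (A = B = 0,
alpha0 = 0) whose experienced-concentration statistics equal the field's
spatial statistics, making its fitness independent of T and L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent import make_sim_config, simulate
from .field import FieldParams, stochastic_environment
from .response import ResponseParams

__all__ = [
    "DegenerateParameterError",
    "FitnessResult",
    "null_params",
    "fitness_from_times",
    "evaluate_fitness",
    "paired_evaluate",
    "relative_fitness",
]


class DegenerateParameterError(RuntimeError):
    """Raised when every replicate hit the safety cap before the threshold."""


@dataclass
class FitnessResult:
    """Per-replicate times-to-threshold and the harmonic-structure fitness."""

    D: np.ndarray
    F: float
    n_truncated: int
    field_seeds: tuple[int, ...]

    @property
    def unreliable(self) -> bool:
        """More than 20% of replicates were truncated at t_max."""
        return self.n_truncated > 0.2 * len(self.D)


def null_params() -> ResponseParams:
    """The non-chemotaxing baseline: never tumbles, kernel switched off."""
    return ResponseParams(alpha0=0.0, beta=1.0, A=0.0, B=0.0, tau=1.0, strategy="null")


def fitness_from_times(D, T: float) -> float:
    """F = T * mean(1/D_i) for a list of times-to-threshold."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("times must be positive")
    return float(T * np.mean(1.0 / D))


def evaluate_fitness(
    params: ResponseParams,
    T: float,
    L: float,
    field_seeds,
    agent_rng=None,
    *,
    stop_factor: float = 50.0,
    t_max_factor: float = 1e4,
    v: float = 1.0,
    ell: float = 100.0,
) -> FitnessResult:
    """Run one simulation per field seed and average the inverse times.

    Each seed initializes (and equilibrates) its own field realization.
    Truncated runs contribute 1/t_max, a conservative lower bound on their
    rate; if every replicate truncates the parameter set is degenerate and
    an error is raised.
    """
    field_seeds = tuple(int(s) for s in np.atleast_1d(field_seeds))
    if not field_seeds:
        raise ValueError("need at least one field seed")
    agent_rng = (
        np.random.default_rng(agent_rng)
        if not isinstance(agent_rng, np.random.Generator)
        else agent_rng
    )
    fp = FieldParams(T=T, L=L, ell=ell)
    tau = None if params.strategy == "null" else params.tau
    cfg = make_sim_config(T, L, tau, v=v, stop_factor=stop_factor, t_max_factor=t_max_factor)
    D = np.empty(len(field_seeds))
    n_trunc = 0
    for i, fs in enumerate(field_seeds):
        env = stochastic_environment(fp, fs)
        res = simulate(params, env, cfg, agent_rng)
        D[i] = res.D
        n_trunc += res.truncated
    if n_trunc == len(field_seeds):
        raise DegenerateParameterError(
            f"all {len(field_seeds)} replicates truncated at t_max={cfg.t_max:g}"
        )
    return FitnessResult(
        D=D, F=fitness_from_times(D, T), n_truncated=n_trunc, field_seeds=field_seeds
    )


def paired_evaluate(
    wt: ResponseParams,
    mut: ResponseParams,
    T: float,
    L: float,
    field_seeds,
    agent_rng=None,
    **kw,
) -> tuple[FitnessResult, FitnessResult]:
    """Evaluate wild type and mutant on identical field realizations.

    Field seed i regenerates bit-identical attractant dynamics for
    replicate i of both genotypes; the agents' own randomness is fresh.
    """
    agent_rng = (
        np.random.default_rng(agent_rng)
        if not isinstance(agent_rng, np.random.Generator)
        else agent_rng
    )
    res_w = evaluate_fitness(wt, T, L, field_seeds, agent_rng, **kw)
    res_m = evaluate_fitness(mut, T, L, field_seeds, agent_rng, **kw)
    return res_w, res_m


def relative_fitness(
    params: ResponseParams,
    T: float,
    L: float,
    field_seeds,
    agent_rng=None,
    **kw,
) -> float:
    """F(params) / F(null baseline) on the same field seeds.

    Both evaluations also replay the same agent random stream, so the
    ratio is a deterministic function of the seeds (and exactly 1 for the
    baseline itself).
    """
    agent_rng = (
        np.random.default_rng(agent_rng)
        if not isinstance(agent_rng, np.random.Generator)
        else agent_rng
    )
    shared = int(agent_rng.integers(2**31))
    res = evaluate_fitness(params, T, L, field_seeds, shared, **kw)
    res_null = evaluate_fitness(null_params(), T, L, field_seeds, shared, **kw)
    return res.F / res_null.F
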