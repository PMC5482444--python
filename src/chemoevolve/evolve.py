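"""Metropolis-Hastings evolutionary optimization of the response parameters.

One generation = one mutation followed by selection.  A single parameter,
chosen uniformly among the strategy's mutable set, is perturbed on a log
scale (|a| -> exp(ln|a| + r), r ~ U(-0.2, 0.2), sign preserved).  Wild type
and mutant are then evaluated on the same freshly drawn field seeds and the
mutant is accepted with probability

    p = 1                               if F_m >= F_w
    p = exp((F_m - F_w) / (U * F_w))    otherwise,  U = 0.005.

The chain runs until the accepted fitness plateaus for ``window`` (600)
generations within a relative tolerance, or a generation cap.  Strategy
constraints are maintained throughout: adaptive mutates only B with A
slaved to -B; inverted keeps B = 0; speculator keeps A > 0 > B.  Parameter
floors (alpha0 > 1e-3 for adaptive/inverted, A and |B| > e^-1 for
speculator, tau > 0.01 for adaptive, beta > 1e-6 everywhere) are enforced
by redrawing r; a proposal below a floor is only rejected if it also moves
away from the floor, so chains initialized below a floor can climb back.

Full-scale runs (10 replicates, 50T stop threshold, 600-generation
convergence window) are hour-scale computations; the "desk" preset
(5 replicates, 5T threshold, capped generations) is a first-class reduced
configuration for exploratory and test use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitness import DegenerateParameterError, evaluate_fitness
from .response import ResponseParams

__all__ = [
    "EvolutionConfig",
    "EvolutionTrace",
    "MUTABLE_PARAMS",
    "PARAM_FLOORS",
    "init_params",
    "mutate",
    "accept_probability",
    "has_converged",
    "run_evolution",
    "summarize_trace",
]

MUTABLE_PARAMS = {
    "adaptive": ("alpha0", "beta", "B", "tau"),
    "inverted": ("alpha0", "beta", "A", "tau"),
    "speculator": ("alpha0", "beta", "A", "B", "tau"),
}

_E_INV = math.exp(-1.0)
_BETA_FLOOR = 1e-6  # numerical safety; no floor is prescribed for beta

PARAM_FLOORS = {
    "adaptive": {"alpha0": 1e-3, "tau": 0.01, "beta": _BETA_FLOOR},
    "inverted": {"alpha0": 1e-3, "beta": _BETA_FLOOR},
    "speculator": {"A": _E_INV, "B": _E_INV, "beta": _BETA_FLOOR},
}


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of one optimization chain.

    U : Metropolis temperature (0.005).
    r_range : half-width of the uniform log-scale mutation step (0.2).
    n_replicates : bacteria per fitness evaluation (10 full scale).
    stop_factor : attractant threshold in units of T (50 full scale).
    window : plateau length for convergence (600 generations).
    eps_rel : relative tolerance defining "constant" fitness (0.01).
    """

    strategy: str
    T: float
    L: float
    seed: int = 0
    U: float = 0.005
    r_range: float = 0.2
    n_replicates: int = 10
    stop_factor: float = 50.0
    t_max_factor: float = 1e4
    window: int = 600
    eps_rel: float = 0.01
    max_generations: int = 100_000
    v: float = 1.0
    ell: float = 100.0
    # additional parameter floors merged over the strategy defaults (the
    # reduced-scale preset floors tau: simulation cost scales as 1/tau and
    # unfloored chains can wander into regions where a single generation
    # takes minutes)
    extra_floors: tuple = ()

    def __post_init__(self) -> None:
        if self.strategy not in MUTABLE_PARAMS:
            raise ValueError(f"cannot evolve strategy {self.strategy!r}")
        if self.U <= 0 or self.r_range <= 0 or self.window < 1:
            raise ValueError("require U > 0, r_range > 0, window >= 1")


def desk_config(strategy: str, T: float, L: float, seed: int = 0, **kw) -> EvolutionConfig:
    """Reduced-scale preset: 5 replicates, 5T threshold, capped generations.

    Also floors tau (0.05 adaptive, 0.1 otherwise) purely for tractability:
    the agent step is tau/20, so simulation cost grows as 1/tau and an
    early-chain excursion to tau ~ 0.01 makes generations minute-scale.
    The floors sit well below every published optimum at the conditions
    studied here (adaptive tau 0.072-0.27; inverted 5.6-8.3; speculator
    39-45), mirroring the full model's own tractability constraints.
    """
    kw.setdefault("n_replicates", 5)
    kw.setdefault("stop_factor", 5.0)
    kw.setdefault("t_max_factor", 100.0)
    kw.setdefault("max_generations", 3000)
    kw.setdefault("extra_floors", (("tau", 0.05 if strategy == "adaptive" else 0.1),))
    return EvolutionConfig(strategy=strategy, T=T, L=L, seed=seed, **kw)


def init_params(strategy: str, T: float, rng) -> ResponseParams:
    """Random initial genotype: parameters ~ U(0, 1) with strategy constraints.

    For the adaptive strategy only B is drawn (A = -B); at T = 1e4 and above
    B starts in U(1, 10) instead, reflecting the much higher sensitivity
    needed there.  Speculator B starts in U(-1, 0).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    alpha0, beta, tau = rng.uniform(0.0, 1.0, size=3)
    if strategy == "adaptive":
        B = rng.uniform(1.0, 10.0) if T >= 1e4 else rng.uniform(0.0, 1.0)
        A = -B
    elif strategy == "inverted":
        A = rng.uniform(0.0, 1.0)
        B = 0.0
    elif strategy == "speculator":
        A = rng.uniform(0.0, 1.0)
        B = rng.uniform(-1.0, 0.0)
    else:
        raise ValueError(f"cannot initialize strategy {strategy!r}")
    return ResponseParams(alpha0=alpha0, beta=beta, A=A, B=B, tau=tau, strategy=strategy)


def _floor_ok(name: str, new_mag: float, old_mag: float, floors: dict) -> bool:
    floor = floors.get(name)
    if floor is None:
        return True
    # below-floor proposals are allowed only if they move toward the floor
    return new_mag > floor or new_mag > old_mag


def mutate(
    params: ResponseParams,
    rng,
    r_range: float = 0.2,
    max_redraws: int = 100,
    extra_floors: dict | None = None,
) -> tuple[ResponseParams, str]:
    """Log-scale mutation of one randomly chosen parameter.

    Returns the mutated parameter set and the name of the mutated
    parameter.  If the redraw budget is exhausted the parent value is kept.
    ``extra_floors`` overlays additional per-parameter magnitude floors.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    strategy = params.strategy
    names = MUTABLE_PARAMS[strategy]
    name = names[rng.integers(len(names))]
    floors = PARAM_FLOORS[strategy]
    if extra_floors:
        floors = {**floors, **{k: max(floors.get(k, 0.0), v) for k, v in extra_floors.items()}}

    old = getattr(params, name)
    sign = -1.0 if old < 0 else 1.0
    old_mag = abs(old)
    new = old
    if old_mag > 0.0:
        for _ in range(max_redraws):
            r = rng.uniform(-r_range, r_range)
            new_mag = math.exp(math.log(old_mag) + r)
            if _floor_ok(name, new_mag, old_mag, floors):
                new = sign * new_mag
                break

    kw = {name: new}
    if strategy == "adaptive" and name == "B":
        kw["A"] = -new
    return params.replace(**kw), name


def accept_probability(F_m: float, F_w: float, U: float = 0.005) -> float:
    """Metropolis rule: 1 if the mutant is at least as fit, else exp(dF/(U F_w))."""
    if F_w <= 0:
        raise ValueError("wild-type fitness must be positive")
    if F_m >= F_w:
        return 1.0
    return math.exp((F_m - F_w) / (U * F_w))


def has_converged(fitness: np.ndarray, window: int = 600, eps_rel: float = 0.01) -> bool:
    """True iff no fitness in the last ``window`` generations beats the
    window-start value by more than ``eps_rel`` relative."""
    fitness = np.asarray(fitness, dtype=float)
    if len(fitness) < window:
        return False
    recent = fitness[-window:]
    return bool(np.max(recent) <= recent[0] * (1.0 + eps_rel))


_PARAM_COLS = ("alpha0", "beta", "A", "B", "tau")


@dataclass
class EvolutionTrace:
    """Per-generation record of one chain plus its configuration.

    ``df`` columns: generation, mutated, the five chain-state parameters
    (after selection), F_w, F_m, accepted, F_chain (the fitness of the
    post-selection state, measured this generation).
    """

    df: pd.DataFrame
    config: EvolutionConfig
    converged: bool

    @property
    def fitness(self) -> np.ndarray:
        return self.df["F_chain"].to_numpy()

    def final_params(self) -> ResponseParams:
        row = self.df.iloc[-1]
        return ResponseParams(
            alpha0=row["alpha0"], beta=row["beta"], A=row["A"], B=row["B"],
            tau=row["tau"], strategy=self.config.strategy,
        )

    def summarize(self, window: int | None = None) -> dict:
        return summarize_trace(self, window=window)


def run_evolution(cfg: EvolutionConfig, progress=None) -> EvolutionTrace:
    """Run one Metropolis chain until convergence or the generation cap.

    Fully reproducible from ``cfg.seed``: a single master generator drives
    initialization, mutation, per-generation field seeds, agent randomness
    and the acceptance coin.  ``progress`` may be a callable taking the
    generation record dict (e.g. for logging).
    """
    rng = np.random.default_rng(cfg.seed)
    wt = init_params(cfg.strategy, cfg.T, rng)
    for pname, floor in dict(cfg.extra_floors).items():
        val = getattr(wt, pname)
        if abs(val) < floor:
            kw = {pname: floor * (1.0 if val >= 0 else -1.0)}
            if cfg.strategy == "adaptive" and pname == "B":
                kw["A"] = -kw[pname]
            wt = wt.replace(**kw)
    eval_kw = dict(
        stop_factor=cfg.stop_factor, t_max_factor=cfg.t_max_factor,
        v=cfg.v, ell=cfg.ell,
    )

    def one_fitness(p, field_seeds, floor_F):
        # a genotype whose every replicate truncates gets the conservative
        # lower-bound fitness T * (1 / t_max)
        try:
            return evaluate_fitness(p, cfg.T, cfg.L, field_seeds, rng, **eval_kw).F
        except DegenerateParameterError:
            return floor_F

    records = []
    fitness_chain = []
    converged = False
    floor_F = 1.0 / cfg.t_max_factor
    for gen in range(1, cfg.max_generations + 1):
        mut, name = mutate(wt, rng, r_range=cfg.r_range, extra_floors=dict(cfg.extra_floors))
        field_seeds = rng.integers(2**31, size=cfg.n_replicates)
        F_w = one_fitness(wt, field_seeds, floor_F)
        F_m = one_fitness(mut, field_seeds, floor_F)

        p_acc = accept_probability(F_m, max(F_w, floor_F), cfg.U)
        accepted = rng.random() < p_acc
        if accepted:
            wt = mut
        F_chain = F_m if accepted else F_w
        rec = {
            "generation": gen,
            "mutated": name,
            **{k: getattr(wt, k) for k in _PARAM_COLS},
            "F_w": F_w,
            "F_m": F_m,
            "accepted": accepted,
            "F_chain": F_chain,
        }
        records.append(rec)
        fitness_chain.append(F_chain)
        if progress is not None:
            progress(rec)
        if gen >= cfg.window and has_converged(fitness_chain, cfg.window, cfg.eps_rel):
            converged = True
            break

    return EvolutionTrace(df=pd.DataFrame(records), config=cfg, converged=converged)


def summarize_trace(trace: EvolutionTrace, window: int | None = None) -> dict:
    """Arithmetic means of the chain parameters over the final window.

    Mirrors the published summaries: each parameter (and B/A, and fitness)
    is averaged over the chain states of the last ``window`` generations.
    """
    window = trace.config.window if window is None else window
    tail = trace.df.tail(window)
    out = {k: float(tail[k].mean()) for k in _PARAM_COLS}
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tail["B"].to_numpy() / tail["A"].to_numpy()
    out["B_over_A"] = float(np.mean(ratio)) if np.all(np.isfinite(ratio)) else float("nan")
    out["F"] = float(tail["F_chain"].mean())
    out["n_generations"] = int(trace.df["generation"].iloc[-1])
    out["converged"] = trace.converged
    return out
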