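"""Single run-and-tumble bacterium in a 1D periodic world.

The agent is a 2-state Markov system (running / tumbling) updated every
dt_b = min(T, L/v, tau/20).  Each step, in order: read the local
concentration, advance the response memory, evaluate the tumble-start rate
alpha, attempt one mode switch (running -> tumbling with probability
1 - exp(-alpha dt_b); tumbling -> running with probability
1 - exp(-beta dt_b), resuming left or right with equal probability), move
if running, accumulate experienced attractant c*dt_b, advance the clock.
Tumbling agents do not move.  A simulation ends when the accumulated
attractant crosses ``stop_attractant`` (time D, the fitness observable) or
at the safety cap t_max (flagged as truncated).

Two engines are provided: a pure-Python reference stepper
(:func:`step_agent` / ``engine="python"``) and the compiled chunked loop in
:mod:`chemoevolve._core` (default).  They consume randomness in the same
order and produce identical trajectories for runs that finish within the
first pre-drawn uniform buffer (2^16 steps); longer compiled runs remain
exactly reproducible from their seeds but part ways with the reference
stream at the first buffer refill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .field import Environment, FieldParams
from .response import KernelState, ResponseParams, init_memory, tumble_start_rate, update_memory

__all__ = [
    "AgentState",
    "SimConfig",
    "SimResult",
    "make_sim_config",
    "step_agent",
    "simulate",
]

MODE_NAMES = {0: "run_right", 1: "run_left", 2: "tumble"}


@dataclass
class AgentState:
    """Position, motility mode, response memory, and accumulated attractant."""

    x: float
    mode: str  # run_left | run_right | tumble
    memory: KernelState
    accumulated: float = 0.0
    t: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Time step, stop threshold and safety cap of one simulation."""

    v: float = 1.0
    dt_b: float = 0.05
    stop_attractant: float = math.inf
    t_max: float = math.inf


def make_sim_config(
    T: float,
    L: float,
    tau: float | None = None,
    v: float = 1.0,
    stop_factor: float = 50.0,
    t_max_factor: float = 1e4,
) -> SimConfig:
    """Build the configuration for a (T, L, tau) triple.

    dt_b = min(T, L/v, tau/20).  Kernel-free (null) agents have no tau
    scale; they step at min(T, L/v)/20 so the experienced-attractant
    integral still resolves the field's spatial variation (a step of a full
    correlation length would alias it).  The stop threshold is
    ``stop_factor * T`` attractant units (50T in the full-scale setting)
    and the safety cap ``t_max_factor * T``.
    """
    if T <= 0 or L <= 0 or v <= 0:
        raise ValueError("T, L, v must be positive")
    if tau is None:
        dt_b = min(T, L / v) / 20.0
    else:
        if tau <= 0:
            raise ValueError("tau must be positive")
        dt_b = min(T, L / v, tau / 20.0)
    return SimConfig(
        v=v,
        dt_b=dt_b,
        stop_attractant=stop_factor * T,
        t_max=t_max_factor * T,
    )


def step_agent(
    agent: AgentState,
    env: Environment,
    params: ResponseParams,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> AgentState:
    """One update of the reference (pure Python) stepper.

    Consumes one uniform for the switching decision and, on a
    tumble-to-run transition only, a second uniform for the new direction.
    Stochastic environments must have been advanced to ``agent.t`` by the
    caller (the :func:`simulate` loop does this).
    """
    c = float(env(agent.x, agent.t))
    memory = update_memory(agent.memory, c, cfg.dt_b, params.tau)
    alpha = tumble_start_rate(params, memory)

    mode = agent.mode
    u = rng.random()
    if mode == "tumble":
        if u < 1.0 - math.exp(-params.beta * cfg.dt_b):
            mode = "run_right" if rng.random() < 0.5 else "run_left"
    else:
        if u < 1.0 - math.exp(-alpha * cfg.dt_b):
            mode = "tumble"

    x = agent.x
    if mode == "run_right":
        x = (x + cfg.v * cfg.dt_b) % env.ell
    elif mode == "run_left":
        x = (x - cfg.v * cfg.dt_b) % env.ell

    return AgentState(
        x=x,
        mode=mode,
        memory=memory,
        accumulated=agent.accumulated + c * cfg.dt_b,
        t=agent.t + cfg.dt_b,
    )


@dataclass
class SimResult:
    """Outcome of one simulation run."""

    D: float
    truncated: bool
    trajectory: pd.DataFrame | None = None
    final_state: AgentState | None = None


def _init_agent(env: Environment, params: ResponseParams, rng: np.random.Generator) -> AgentState:
    x0 = rng.uniform(0.0, env.ell)
    mode = "run_right" if rng.random() < 0.5 else "run_left"
    c0 = float(env(x0, 0.0))
    return AgentState(x=x0, mode=mode, memory=init_memory(params, c0), t=0.0)


def simulate(
    params: ResponseParams,
    env: Environment,
    cfg: SimConfig,
    rng=None,
    *,
    record: bool = False,
    record_every: int = 1,
    t_end: float | None = None,
    engine: str = "compiled",
) -> SimResult:
    """Run one bacterium until the attractant threshold, t_end, or t_max.

    Stochastic environments are reset to their seeded realization at the
    start of every call, so repeated calls with the same agent ``rng`` seed
    are fully reproducible and a field seed defines the same environment
    for different parameter sets.  ``t_end`` (defaults to ``cfg.t_max``)
    caps the run; crossing the threshold sets D at the step-end time.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if env.tag == "stochastic":
        env.reset()
    t_cap = cfg.t_max if t_end is None else min(t_end, cfg.t_max)
    if not np.isfinite(t_cap) and not np.isfinite(cfg.stop_attractant):
        raise ValueError("either stop_attractant or t_end must be finite")
    if engine == "python":
        return _simulate_python(params, env, cfg, rng, record, record_every, t_cap)
    return _simulate_compiled(params, env, cfg, rng, record, record_every, t_cap)


def _simulate_python(params, env, cfg, rng, record, record_every, t_cap):
    agent = _init_agent(env, params, rng)
    rows = []
    n = 0
    truncated = False
    while True:
        if agent.accumulated >= cfg.stop_attractant:
            break
        if agent.t >= t_cap - 1e-12 * cfg.dt_b:
            truncated = np.isfinite(cfg.stop_attractant)
            break
        env.advance_to(agent.t)
        agent = step_agent(agent, env, params, cfg, rng)
        n += 1
        agent.t = n * cfg.dt_b  # counter-based clock, no accumulation drift
        if record and n % record_every == 0:
            rows.append(
                (
                    agent.t,
                    agent.x,
                    agent.mode,
                    float(env(agent.x, agent.t)),
                    tumble_start_rate(params, agent.memory),
                    agent.accumulated,
                )
            )
    traj = (
        pd.DataFrame(rows, columns=["t", "x", "mode", "c", "alpha", "accumulated"])
        if record
        else None
    )
    return SimResult(D=agent.t, truncated=truncated, trajectory=traj, final_state=agent)


_FIRST_CHUNK = 1 << 16
_MAX_CHUNK = 1 << 21


def _simulate_compiled(params, env, cfg, rng, record, record_every, t_cap):
    ell = env.ell
    tau = params.tau
    dt_b = cfg.dt_b
    e_dec = math.exp(-dt_b / tau)
    k1 = tau * (1.0 - e_dec)
    k2 = tau * tau - e_dec * (tau * tau + tau * dt_b)
    p_beta = 1.0 - math.exp(-params.beta * dt_b)

    if env.tag == "stochastic":
        env_kind = _core.ENV_STOCHASTIC
        fp: FieldParams = env.field_params
        field_rng = env._rng  # continues the stream used for equilibration
        X = env._state.X.copy()
        Y = env._state.Y.copy()
        ep = np.zeros(4)
        dt_c = fp.dt_c
        f_decay = 1.0 - dt_c / fp.T
        f_scale = fp.noise_scale
    else:
        env_kind = {
            "constant": _core.ENV_CONSTANT,
            "step": _core.ENV_STEP,
            "two-gaussian": _core.ENV_TWO_GAUSSIAN,
        }[env.tag]
        field_rng = None
        X = np.zeros(1)
        Y = np.zeros(1)
        pl = env.payload
        if env.tag == "constant":
            ep = np.array([pl["c0"], 0.0, 0.0, 0.0])
        elif env.tag == "step":
            ep = np.array([pl["c0"], pl["t_on"], pl["t_off"], 0.0])
        else:
            ep = np.array([pl["period"], pl["c1"], pl["c2"], pl["sigma"]])
        dt_c = 1.0
        f_decay = 0.0
        f_scale = 0.0

    # initial conditions drawn in the same order as the python engine
    x = rng.uniform(0.0, ell)
    dirn = 1.0 if rng.random() < 0.5 else -1.0
    tumbling = 0
    c0 = float(env(x, 0.0))
    mem0 = init_memory(params, c0)
    M1, M2 = mem0.M1, mem0.M2

    n_steps = 0
    f_used = 0
    n_field_applied = 0
    acc = 0.0
    field_noise = np.zeros((0, 2, X.shape[0]))
    uniforms = np.zeros(0)
    u_used = 0
    chunk = _FIRST_CHUNK
    rec_chunks = []
    truncated = False
    rec_dummy = np.zeros(0)
    rec_mode_dummy = np.zeros(0, dtype=np.int64)

    uniforms = rng.random(2 * chunk + 2)
    if env_kind == _core.ENV_STOCHASTIC:
        field_noise = field_rng.standard_normal((int(chunk * dt_b / dt_c) + 2, 2, X.shape[0]))

    while True:
        if record:
            # one call can take up to ~2*chunk steps (1 uniform per running
            # step, 2 only on tumble exits), so size for the worst case
            n_rec = 2 * chunk // record_every + 4
            rec_t = np.zeros(n_rec)
            rec_x = np.zeros(n_rec)
            rec_mode = np.zeros(n_rec, dtype=np.int64)
            rec_c = np.zeros(n_rec)
            rec_alpha = np.zeros(n_rec)
            rec_acc = np.zeros(n_rec)
        else:
            rec_t = rec_x = rec_c = rec_alpha = rec_acc = rec_dummy
            rec_mode = rec_mode_dummy

        (
            status, x, dirn, tumbling, M1, M2, acc, n_steps,
            f_used, n_field_applied, u_used, rec_ptr,
        ) = _core.run_chunk(
            x, dirn, tumbling, M1, M2, acc, n_steps,
            env_kind, ep, X, Y, ell,
            dt_b, cfg.v,
            params.alpha0, params.A / tau, params.B / tau**2,
            e_dec, k1, k2, p_beta,
            cfg.stop_attractant, t_cap,
            field_noise, f_used, n_field_applied, dt_c, f_decay, f_scale,
            uniforms, u_used,
            record_every if record else 0,
            rec_t, rec_x, rec_mode, rec_c, rec_alpha, rec_acc,
        )
        if record and rec_ptr:
            rec_chunks.append(
                (rec_t[:rec_ptr].copy(), rec_x[:rec_ptr].copy(), rec_mode[:rec_ptr].copy(),
                 rec_c[:rec_ptr].copy(), rec_alpha[:rec_ptr].copy(), rec_acc[:rec_ptr].copy())
            )
        if status == 1:
            break
        if status == 2:
            truncated = np.isfinite(cfg.stop_attractant)
            break
        chunk = min(chunk * 4, _MAX_CHUNK)
        if status == 0:
            # agent uniforms exhausted; unused ones may be discarded (the
            # agent stream is private to this run)
            uniforms = rng.random(2 * chunk + 2)
            u_used = 0
        elif status == 3:
            # field noise exhausted; never discard unused rows -- the k-th
            # field update must consume the k-th draw of the field stream
            # regardless of agent parameters (paired-fitness contract)
            field_noise = field_rng.standard_normal(
                (int(chunk * dt_b / dt_c) + 2, 2, X.shape[0])
            )
            f_used = 0

    traj = None
    if record:
        if rec_chunks:
            cols = [np.concatenate(parts) for parts in zip(*rec_chunks)]
        else:
            cols = [np.zeros(0)] * 6
        traj = pd.DataFrame(
            {
                "t": cols[0],
                "x": cols[1],
                "mode": pd.Series(cols[2]).map(MODE_NAMES),
                "c": cols[3],
                "alpha": cols[4],
                "accumulated": cols[5],
            }
        )
    mode = MODE_NAMES[2 if tumbling else (0 if dirn > 0 else 1)]
    final = AgentState(
        x=x, mode=mode, memory=KernelState(M1=M1, M2=M2), accumulated=acc, t=n_steps * dt_b
    )
    return SimResult(D=n_steps * dt_b, truncated=truncated, trajectory=traj, final_state=final)
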