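"""Diagnostic analyses of the chemotactic response model.

Four experiment families:

* deterministic step-response time courses of the tumble-start rate alpha
  under attractant addition/removal (with an exact closed form as oracle);
* least-squares recovery of the five response parameters from an observed
  tumbling time series, modeling the observable as the quasi-steady
  tumbling probability alpha/(alpha + beta) of the 2-state system;
* the two-antiphase-Gaussian tracking experiment contrasting the
  exploitation of the adaptive strategy with the exploration of the
  speculator strategy (circular position statistics vs oscillation phase);
* straight-line traversal of a static 3D field with random re-orientation
  every distance 2*ell, showing the experienced-concentration
  autocorrelation matches the 1D field's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import least_squares

from .agent import SimConfig, simulate
from .field import Environment, Field3D, concentration_3d, two_gaussian_environment
from .response import ResponseParams, init_memory, tumble_start_rate, update_memory

__all__ = [
    "TimeSeries",
    "FitResult",
    "GaussianWorldResult",
    "step_response_timecourse",
    "step_alpha_closed_form",
    "tumble_probability",
    "fit_step_response",
    "two_gaussian_experiment",
    "departure_theta",
    "traverse_3d",
    "autocorrelation",
    "circular_mean",
    "circular_std",
]


@dataclass
class TimeSeries:
    """Sampled values over strictly increasing times."""

    t: np.ndarray
    y: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal lengths")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


# ---------------------------------------------------------------------------
# Step responses
# ---------------------------------------------------------------------------


def step_response_timecourse(
    params: ResponseParams,
    c0: float = 1.0,
    t_on: float = 50.0,
    t_off: float = 350.0,
    t_end: float = 600.0,
    dt: float | None = None,
) -> TimeSeries:
    """Deterministic alpha(t) under a spatially uniform concentration step.

    The response memory is advanced by the exact piecewise-constant
    recursion at resolution ``dt`` (default tau/20, the agent's own cap),
    with no agent motion.  Concentration is held left-continuously over
    each step, so step edges aligned to the grid are exact.
    """
    if dt is None:
        dt = params.tau / 20.0
    if dt > params.tau / 20.0 + 1e-12:
        raise ValueError("dt must not exceed tau/20")
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    mem = init_memory(params, 0.0)
    alpha = np.empty(n + 1)
    alpha[0] = params.alpha0
    for k in range(1, n + 1):
        c = c0 if t_on <= t[k - 1] < t_off else 0.0
        mem = update_memory(mem, c, dt, params.tau)
        alpha[k] = tumble_start_rate(params, mem)
    return TimeSeries(t=t, y=alpha, meta={"observable": "alpha", "c0": c0})


def _step_on_integral(params: ResponseParams, u) -> np.ndarray:
    """int_0^u R(s) ds response to a unit step of age u (vectorized, u >= 0)."""
    u = np.asarray(u, dtype=float)
    tau = params.tau
    e = np.exp(-u / tau)
    return params.A * (1.0 - e) + params.B * (1.0 - (1.0 + u / tau) * e)


def step_alpha_closed_form(
    params: ResponseParams,
    c0: float,
    t_on: float,
    t_off: float,
    t,
) -> np.ndarray | float:
    """Exact alpha(t) for the on/off concentration step, by superposition."""
    t = np.asarray(t, dtype=float)
    drive = np.zeros_like(t)
    on = t >= t_on
    drive[on] = c0 * _step_on_integral(params, t[on] - t_on)
    off = t >= t_off
    drive[off] -= c0 * _step_on_integral(params, t[off] - t_off)
    out = np.maximum(0.0, params.alpha0 + drive)
    return float(out) if out.ndim == 0 else out


def tumble_probability(alpha, beta: float, t=None) -> np.ndarray:
    """Tumbling probability of the 2-state system driven by alpha(t).

    Integrates the master equation dp/dt = alpha(t) (1 - p) - beta p
    exactly for alpha held piecewise constant between the sample times
    ``t`` (initial condition: the pre-series steady state).  With ``t``
    omitted the quasi-steady occupancy alpha/(alpha + beta) is returned;
    note that the quasi-steady value is invariant under a common rescaling
    of all four rate parameters, so only the full dynamics pin the
    absolute rate scale.
    """
    alpha = np.asarray(alpha, dtype=float)
    if t is None:
        return alpha / (alpha + beta)
    from ._core import two_state_occupancy

    t = np.asarray(t, dtype=float)
    rate = alpha + beta
    p_eq = alpha / rate
    # alpha is held left-continuously over each sample interval
    decay = np.exp(-rate[:-1] * np.diff(t))
    return two_state_occupancy(p_eq, decay)


# ---------------------------------------------------------------------------
# Kernel fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a step-response parameter fit."""

    params: ResponseParams
    ssr: float
    b_over_a: float
    success: bool
    degenerate: bool
    n_starts: int


def _model_series(theta_log, c0, t_on, t_off, t, observable):
    alpha0, beta, A, negB, tau = np.exp(theta_log)
    p = ResponseParams(alpha0=alpha0, beta=beta, A=A, B=-negB, tau=tau, strategy="speculator")
    alpha = step_alpha_closed_form(p, c0, t_on, t_off, t)
    return tumble_probability(alpha, beta, t) if observable == "probability" else alpha


def fit_step_response(
    data: TimeSeries,
    c0: float,
    t_on: float,
    t_off: float,
    init: ResponseParams | None = None,
    observable: str = "probability",
    n_starts: int = 8,
    rng=None,
) -> FitResult:
    """Nonlinear least squares for (alpha0, beta, A, B, tau) from a tumbling series.

    By default the observable is modeled as the quasi-steady tumbling
    probability alpha(t)/(alpha(t) + beta) -- this is what makes beta
    identifiable from a probability trace; ``observable="rate"`` fits raw
    alpha instead.  Parameters are fitted in log space (B through its
    magnitude, keeping the speculator signs A > 0 > B), restarting from
    ``init`` plus random log-perturbed initializations and keeping the
    best solution.
    """
    if observable not in ("probability", "rate"):
        raise ValueError("observable must be 'probability' or 'rate'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t, y = data.t, data.y

    if init is None:
        init = ResponseParams(
            alpha0=0.1, beta=0.1, A=10.0, B=-5.0, tau=(t_off - t_on) / 4.0,
            strategy="speculator",
        )
    x0 = np.log([init.alpha0, init.beta, init.A, -init.B, init.tau])

    def resid(theta):
        return _model_series(theta, c0, t_on, t_off, t, observable) - y

    best = None
    starts = [x0] + [x0 + rng.normal(0.0, 1.0, size=5) for _ in range(n_starts - 1)]
    for s in starts:
        try:
            sol = least_squares(resid, s, method="trf", max_nfev=2000)
        except (ValueError, FloatingPointError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    alpha0, beta, A, negB, tau = np.exp(best.x)
    fitted = ResponseParams(
        alpha0=alpha0, beta=beta, A=A, B=-negB, tau=tau, strategy="speculator"
    )
    model = _model_series(best.x, c0, t_on, t_off, t, observable)
    ssr = float(np.sum((model - y) ** 2))
    span = float(np.ptp(y))
    # a flat series pins only alpha0/beta; amplitudes are then meaningless
    degenerate = span < 1e-3 or (A + negB) * c0 < 1e-6
    return FitResult(
        params=fitted,
        ssr=ssr,
        b_over_a=fitted.B / fitted.A,
        success=bool(best.success),
        degenerate=bool(degenerate),
        n_starts=len(starts),
    )


# ---------------------------------------------------------------------------
# Two oscillating Gaussians
# ---------------------------------------------------------------------------


def circular_mean(x, ell: float) -> float:
    ang = 2.0 * np.pi * np.asarray(x, float) / ell
    m = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    r = (m * ell / (2.0 * np.pi)) % ell
    return 0.0 if r >= ell else r  # float mod of a tiny negative can hit ell

def circular_std(x, ell: float) -> float:
    ang = 2.0 * np.pi * np.asarray(x, float) / ell
    R = math.hypot(float(np.mean(np.sin(ang))), float(np.mean(np.cos(ang))))
    R = min(max(R, 1e-12), 1.0)
    return math.sqrt(-2.0 * math.log(R)) * ell / (2.0 * np.pi)


@dataclass
class GaussianWorldResult:
    """Phase-folded position statistics of agents in the two-Gaussian world."""

    theta: np.ndarray
    mean_x: np.ndarray
    std_x: np.ndarray
    per_agent_mean: np.ndarray  # (n_agents, n_bins)
    ell: float
    period: float


def two_gaussian_experiment(
    params: ResponseParams,
    n_agents: int = 50,
    n_periods: int = 2,
    rng=None,
    env: Environment | None = None,
    burn_periods: int = 1,
    n_bins: int = 50,
    L_match: float = 20.0,
    sample_dt: float = 1.0,
) -> GaussianWorldResult:
    """Track many independent agents through the oscillating two-peak world.

    Each agent runs ``burn_periods + n_periods`` oscillation periods; the
    burn-in period lets agents find and settle on the initially dominant
    peak before positions are folded by phase theta = t mod period.
    Position statistics are circular (the world is periodic).  The agent
    time step follows the usual rule with the world's matched correlation
    scales, dt_b = min(L_match / v, tau / 20).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if env is None:
        env = two_gaussian_environment()
    period = env.payload["period"]
    dt_b = min(L_match, params.tau / 20.0)
    cfg = SimConfig(v=1.0, dt_b=dt_b, stop_attractant=math.inf, t_max=math.inf)
    t_total = (burn_periods + n_periods) * period
    record_every = max(1, int(round(sample_dt / dt_b)))

    edges = np.linspace(0.0, period, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_agent_sin = np.zeros((n_agents, n_bins))
    per_agent_cos = np.zeros((n_agents, n_bins))
    pooled_sin = np.zeros(n_bins)
    pooled_cos = np.zeros(n_bins)
    counts = np.zeros(n_bins)

    for a in range(n_agents):
        res = simulate(
            params, env, cfg, rng, record=True, record_every=record_every, t_end=t_total
        )
        tr = res.trajectory
        keep = tr["t"].to_numpy() >= burn_periods * period
        theta = np.mod(tr["t"].to_numpy()[keep], period)
        x = tr["x"].to_numpy()[keep]
        ang = 2.0 * np.pi * x / env.ell
        idx = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
        s = np.bincount(idx, weights=np.sin(ang), minlength=n_bins)
        c = np.bincount(idx, weights=np.cos(ang), minlength=n_bins)
        n = np.bincount(idx, minlength=n_bins)
        per_agent_sin[a] = s
        per_agent_cos[a] = c
        pooled_sin += s
        pooled_cos += c
        counts += n

    def to_pos(s, c):
        r = np.mod(np.arctan2(s, c) * env.ell / (2.0 * np.pi), env.ell)
        return np.where(r >= env.ell, 0.0, r)

    mean_x = to_pos(pooled_sin, pooled_cos)
    R = np.sqrt(pooled_sin**2 + pooled_cos**2) / np.maximum(counts, 1)
    R = np.clip(R, 1e-12, 1.0)
    std_x = np.sqrt(-2.0 * np.log(R)) * env.ell / (2.0 * np.pi)
    per_agent_mean = to_pos(per_agent_sin, per_agent_cos)
    return GaussianWorldResult(
        theta=centers, mean_x=mean_x, std_x=std_x, per_agent_mean=per_agent_mean,
        ell=env.ell, period=period,
    )


def departure_theta(
    result: GaussianWorldResult,
    from_center: float = 25.0,
    to_center: float = 75.0,
) -> float:
    """Smallest phase at which the population mean is circularly closer to
    the growing peak than to the declining one (infinity if never)."""

    def circ_dist(a, b, ell):
        return np.abs(np.mod(a - b + ell / 2.0, ell) - ell / 2.0)

    d_from = circ_dist(result.mean_x, from_center, result.ell)
    d_to = circ_dist(result.mean_x, to_center, result.ell)
    crossed = np.nonzero(d_to < d_from)[0]
    return float(result.theta[crossed[0]]) if crossed.size else math.inf


# ---------------------------------------------------------------------------
# 3D traversal
# ---------------------------------------------------------------------------


def traverse_3d(
    fld: Field3D,
    v: float = 1.0,
    n_segments: int = 50,
    dt: float = 0.5,
    rng=None,
) -> TimeSeries:
    """Concentration experienced on straight runs through a static 3D field.

    The walker moves at speed v along a uniformly random direction,
    redrawing the direction after each traversed distance 2*ell; positions
    wrap periodically on every axis and the field is sampled every
    dx = v*dt.
    """
    if not hasattr(rng, "standard_normal"):
        rng = np.random.default_rng(rng)
    ell = fld.ell
    pos = rng.uniform(0.0, ell, size=3)
    n_per_seg = int(round(2.0 * ell / (v * dt)))
    chunks_t, chunks_c = [], []
    t0 = 0.0
    for _ in range(n_segments):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        steps = np.arange(1, n_per_seg + 1)[:, None] * (v * dt) * d[None, :]
        path = np.mod(pos + steps, ell)
        chunks_c.append(concentration_3d(fld, path))
        chunks_t.append(t0 + np.arange(1, n_per_seg + 1) * dt)
        pos = path[-1]
        t0 += n_per_seg * dt
    return TimeSeries(
        t=np.concatenate(chunks_t),
        y=np.concatenate(chunks_c),
        meta={"dx": v * dt, "ell": ell},
    )


def autocorrelation(series: TimeSeries, max_lag: int) -> TimeSeries:
    """Normalized autocovariance r(k), mean-removed, biased, r(0) = 1."""
    from statsmodels.tsa.stattools import acf

    if max_lag >= len(series.y):
        raise ValueError("max_lag must be smaller than the series length")
    r = acf(series.y, nlags=max_lag, fft=True, adjusted=False)
    dt = float(series.t[1] - series.t[0]) if len(series.t) > 1 else 1.0
    return TimeSeries(t=np.arange(max_lag + 1) * dt, y=r, meta={"kind": "acf"})
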