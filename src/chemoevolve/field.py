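"""Stochastic and deterministic attractant environments.

The stochastic attractant distribution is a truncated Fourier series on a
periodic 1D world of length ``ell``:

    c(x, t) = max(0, sum_{p=1}^{p*} X_p(t) cos(2 pi p x / ell)
                                  + Y_p(t) sin(2 pi p x / ell))

where each mode weight follows a discretized Ornstein-Uhlenbeck (AR(1))
process updated every ``dt_c = T/100``:

    X_p(t + dt_c) = X_p(t) (1 - dt_c/T) + eta sqrt(2 dt_c / (T p*))

with eta a standard normal draw, independently per mode and per weight.
``T`` is the correlation time of every weight, ``p* = ell/L`` the highest
spatial mode, and ``L = ell/p*`` the nominal correlation length (peak
spacing).  At stationarity each weight has variance ~ 1/p*, the unclipped
field has unit variance, and the clipped field has mean ~ 1/sqrt(2 pi)
independent of T and L.

A static 3D analogue (for the straight-line traversal experiment) and the
deterministic test environments (concentration steps, two antiphase
oscillating Gaussians) live here as well, all behind a common
``Environment`` contract mapping (position, time) -> concentration >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "FieldParams",
    "FieldState",
    "Field3D",
    "Environment",
    "init_field",
    "update_field",
    "concentration",
    "spatial_covariance",
    "stationary_weight_variance",
    "make_field_3d",
    "concentration_3d",
    "stochastic_environment",
    "constant_environment",
    "step_environment",
    "two_gaussian_environment",
]


@dataclass(frozen=True)
class FieldParams:
    """Parameters of the stochastic attractant field.

    T : correlation time of the mode weights.
    L : nominal correlation length; sets the highest mode p* = ell/L.
    ell : world length (periodic), default 100.
    """

    T: float
    L: float
    ell: float = 100.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.ell <= 0:
            raise ValueError(f"ell must be positive, got {self.ell}")
        if not (0 < self.L <= self.ell):
            raise ValueError(f"L must lie in (0, ell], got {self.L}")
        ratio = self.ell / self.L
        if abs(ratio - round(ratio)) > 1e-9:
            warnings.warn(
                f"ell/L = {ratio:g} is not an integer; "
                f"rounding the highest mode to p* = {max(1, round(ratio))}",
                stacklevel=3,
            )

    @property
    def p_star(self) -> int:
        """Highest spatial mode number, ell/L rounded to an integer >= 1."""
        return max(1, int(round(self.ell / self.L)))

    @property
    def dt_c(self) -> float:
        """Field update interval, T/100."""
        return self.T / 100.0

    @property
    def noise_scale(self) -> float:
        """Std of the per-update noise kick, sqrt(2 dt_c / (T p*))."""
        return np.sqrt(2.0 * self.dt_c / (self.T * self.p_star))


@dataclass
class FieldState:
    """Mode weights and clock of a stochastic field realization."""

    X: np.ndarray
    Y: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must have the same length")


def init_field(params: FieldParams, seed=None, t_eq: float | None = None) -> FieldState:
    """Create a field with all weights zero and equilibrate it.

    Weights start at zero at time ``-t_eq`` (default ``t_eq = 2T``, at least
    the correlation time) and are advanced to t = 0 by repeated
    :func:`update_field` so the returned state is approximately stationary.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if t_eq is None:
        t_eq = 2.0 * params.T
    n_eq = int(round(t_eq / params.dt_c))
    if n_eq == 0:
        return FieldState(X=np.zeros(params.p_star), Y=np.zeros(params.p_star), t=0.0)
    # run the AR(1) recursion from zero initial weights; lfilter applies
    # w_k = decay * w_{k-1} + scale * eta_k, identical to repeated
    # update_field calls with the same draws
    decay = 1.0 - params.dt_c / params.T
    eta = rng.standard_normal((n_eq, 2, params.p_star))
    series = lfilter([params.noise_scale], [1.0, -decay], eta, axis=0)
    return FieldState(X=series[-1, 0].copy(), Y=series[-1, 1].copy(), t=0.0)


def update_field(state: FieldState, params: FieldParams, rng: np.random.Generator) -> FieldState:
    """Advance the mode weights by one AR(1) update of length dt_c."""
    decay = 1.0 - params.dt_c / params.T
    scale = params.noise_scale
    eta = rng.standard_normal((2, params.p_star))
    return FieldState(
        X=state.X * decay + scale * eta[0],
        Y=state.Y * decay + scale * eta[1],
        t=state.t + params.dt_c,
    )


def concentration(state: FieldState, params: FieldParams, x) -> np.ndarray | float:
    """Clipped attractant concentration at position(s) ``x``.

    Positions are wrapped modulo ``ell``; the mode sum is clipped at zero.
    """
    x = np.mod(np.asarray(x, dtype=float), params.ell)
    p = np.arange(1, params.p_star + 1)
    phase = 2.0 * np.pi * np.multiply.outer(x, p) / params.ell
    unclipped = np.cos(phase) @ state.X + np.sin(phase) @ state.Y
    out = np.maximum(0.0, unclipped)
    return float(out) if out.ndim == 0 else out


def stationary_weight_variance(params: FieldParams) -> float:
    """Exact stationary variance of one AR(1) mode weight.

    For X <- X(1-d) + eta*s with d = dt_c/T and s^2 = 2 dt_c/(T p*):
    var = s^2 / (1 - (1-d)^2) = 1 / (p* (1 - d/2)), slightly above 1/p*.
    """
    d = params.dt_c / params.T
    return 1.0 / (params.p_star * (1.0 - d / 2.0))


def spatial_covariance(params: FieldParams, d) -> np.ndarray | float:
    """Stationary spatial covariance of the *unclipped* field at separation d.

    Independent modes sum: C(d) = var_w * sum_p cos(2 pi p d / ell), with
    var_w the exact stationary weight variance (~1/p*).
    """
    d = np.asarray(d, dtype=float)
    p = np.arange(1, params.p_star + 1)
    out = stationary_weight_variance(params) * np.cos(
        2.0 * np.pi * np.multiply.outer(d, p) / params.ell
    ).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# 3D static field
# ---------------------------------------------------------------------------


@dataclass
class Field3D:
    """Static 3D attractant field on a periodic cube of edge ``ell``.

    Weights X3[p-1, q-1, r-1], Y3[...] multiply cos/sin of
    2 pi (p x + q y + r z) / ell for p, q, r = 1..p*.  Drawn i.i.d. normal
    with variance 1/p*^3 so the covariance along each axis matches the 1D
    field's closed form.  ``clip`` controls whether evaluation clips at 0.
    """

    X3: np.ndarray
    Y3: np.ndarray
    ell: float
    clip: bool = False


def make_field_3d(params: FieldParams, seed=None, clip: bool = False) -> Field3D:
    """Draw a static isotropic 3D field matching the 1D correlation length."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = params.p_star
    sigma = p ** -1.5
    return Field3D(
        X3=sigma * rng.standard_normal((p, p, p)),
        Y3=sigma * rng.standard_normal((p, p, p)),
        ell=params.ell,
        clip=clip,
    )


def concentration_3d(fld: Field3D, pos) -> np.ndarray | float:
    """Field value at 3D position(s); ``pos`` has shape (3,) or (n, 3)."""
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    p = np.arange(1, fld.X3.shape[0] + 1)
    # phase[n, i, j, k] = 2 pi (p_i x_n + p_j y_n + p_k z_n) / ell
    ax = np.multiply.outer(pos[:, 0], p)[:, :, None, None]
    ay = np.multiply.outer(pos[:, 1], p)[:, None, :, None]
    az = np.multiply.outer(pos[:, 2], p)[:, None, None, :]
    phase = 2.0 * np.pi * (ax + ay + az) / fld.ell
    out = np.einsum("nijk,ijk->n", np.cos(phase), fld.X3) + np.einsum(
        "nijk,ijk->n", np.sin(phase), fld.Y3
    )
    if fld.clip:
        out = np.maximum(0.0, out)
    return float(out[0]) if out.shape[0] == 1 and np.asarray(pos).ndim == 2 else out


# ---------------------------------------------------------------------------
# Environment contract
# ---------------------------------------------------------------------------


@dataclass
class Environment:
    """Common contract: a tagged callable (position, time) -> concentration >= 0.

    ``tag`` is one of {"stochastic", "constant", "step", "two-gaussian"}.
    Stochastic environments carry their FieldParams/seed and a mutable
    FieldState advanced by :meth:`advance_to`; deterministic environments
    ignore it.  ``payload`` holds the numeric parameters the fast simulation
    path needs.
    """

    tag: str
    ell: float
    fn: Callable[[float, float], float]
    payload: dict = field(default_factory=dict)
    field_params: FieldParams | None = None
    field_seed: int | None = None
    _state: FieldState | None = None
    _rng: np.random.Generator | None = None
    _n_updates: int = 0

    def __call__(self, x, t: float):
        c = self.fn(x, t)
        return np.maximum(0.0, c)

    # -- stochastic-field plumbing ---------------------------------------
    def reset(self) -> None:
        """(Re)initialize the stochastic field realization from its seed."""
        if self.tag != "stochastic":
            return
        self._rng = np.random.default_rng(self.field_seed)
        self._state = init_field(self.field_params, self._rng)
        self._n_updates = 0

    def advance_to(self, t: float) -> None:
        """Apply every field update scheduled at or before time ``t``.

        Updates are counted so the k-th update fires when k*dt_c <= t,
        matching the compiled engine's schedule exactly (no float drift).
        """
        if self.tag != "stochastic":
            return
        if self._state is None:
            self.reset()
        dt_c = self.field_params.dt_c
        while (self._n_updates + 1) * dt_c <= t * (1.0 + 1e-12) + 1e-12:
            self._state = update_field(self._state, self.field_params, self._rng)
            self._n_updates += 1

    @property
    def state(self) -> FieldState | None:
        return self._state


def stochastic_environment(params: FieldParams, seed: int) -> Environment:
    """Dynamic stochastic attractant field as an Environment."""
    env = Environment(
        tag="stochastic",
        ell=params.ell,
        fn=lambda x, t: 0.0,  # replaced below; needs self-reference
        field_params=params,
        field_seed=seed,
    )
    env.fn = lambda x, t: concentration(env._state, params, x)
    env.reset()
    return env


def constant_environment(c0: float, ell: float = 100.0) -> Environment:
    """Spatially and temporally uniform concentration c0."""
    if c0 < 0:
        raise ValueError("concentration must be >= 0")
    return Environment(
        tag="constant", ell=ell, fn=lambda x, t: c0 * np.ones_like(np.asarray(x, float)),
        payload={"c0": c0},
    )


def step_environment(c0: float, t_on: float, t_off: float, ell: float = 100.0) -> Environment:
    """Uniform concentration c0 present for t_on <= t < t_off, else 0."""
    if not t_on < t_off:
        raise ValueError("require t_on < t_off")

    def fn(x, t):
        c = c0 if (t_on <= t < t_off) else 0.0
        return c * np.ones_like(np.asarray(x, float))

    return Environment(
        tag="step", ell=ell, fn=fn, payload={"c0": c0, "t_on": t_on, "t_off": t_off}
    )


def _wrapped_gaussian(x, center: float, sigma: float, ell: float):
    d = np.mod(np.asarray(x, float) - center + ell / 2.0, ell) - ell / 2.0
    return np.exp(-0.5 * (d / sigma) ** 2)


def two_gaussian_environment(
    period: float = 5000.0,
    centers: tuple[float, float] = (25.0, 75.0),
    sigma_g: float = 3.0,
    ell: float = 100.0,
) -> Environment:
    """Two Gaussian attractant bumps oscillating in amplitude in antiphase.

    Amplitudes A1(t) = (1 + cos(2 pi t / period)) / 2 and A2 = 1 - A1, so the
    left bump is at full height (peak value 1) at phase 0 and extinguished at
    half period.  Bumps are evaluated with periodic wrapping.
    """
    c1, c2 = centers
    if not (0 <= c1 < ell and 0 <= c2 < ell):
        raise ValueError("centers must lie within [0, ell)")

    def fn(x, t):
        a1 = 0.5 * (1.0 + np.cos(2.0 * np.pi * t / period))
        return a1 * _wrapped_gaussian(x, c1, sigma_g, ell) + (1.0 - a1) * _wrapped_gaussian(
            x, c2, sigma_g, ell
        )

    return Environment(
        tag="two-gaussian",
        ell=ell,
        fn=fn,
        payload={"period": period, "c1": c1, "c2": c2, "sigma": sigma_g},
    )
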