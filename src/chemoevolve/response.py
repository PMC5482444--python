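"""Chemotactic response kernel and the tumbling-rate convolution.

The tumble-initiation rate of the bacterium is a clipped linear response to
the attractant history it has experienced:

    alpha(t) = max(0, alpha0 + int_0^inf R(s) c(t - s) ds)

with the bilobed kernel R(s) = (A/tau + B s/tau^2) exp(-s/tau).  The three
strategies are encoded as sign constraints on (A, B):

* adaptive   : A = -B < 0 -- equal-area lobes, zero net kernel area, hence
               perfect adaptation (steady-state rate alpha0 under any
               constant concentration);
* inverted   : A > 0, B = 0 -- single positive lobe, rate follows absolute
               concentration;
* speculator : A > 0 > B, typically |B| < |A| -- compares the recent past
               with a long-term average; net area A + B > 0;
* null       : A = B = 0 -- non-chemotaxing baseline.

The convolution is evaluated exactly for piecewise-constant concentration
via two exponentially weighted memory integrals

    M1(t) = int_0^inf e^{-s/tau} c(t-s) ds
    M2(t) = int_0^inf s e^{-s/tau} c(t-s) ds

so that int R c = (A/tau) M1 + (B/tau^2) M2, updated recursively in O(1)
per step with no within-step discretization error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "STRATEGIES",
    "ResponseParams",
    "KernelState",
    "kernel_value",
    "kernel_integral",
    "init_memory",
    "update_memory",
    "convolution_value",
    "tumble_start_rate",
]

STRATEGIES = ("adaptive", "inverted", "speculator", "null")


@dataclass(frozen=True)
class ResponseParams:
    """The five response parameters plus the strategy tag (the genotype).

    alpha0 : basal tumble-start rate (1/time), >= 0.
    beta   : tumble-stop rate (1/time), > 0; 1/beta is the mean tumble length.
    A, B   : kernel amplitudes (1/(concentration*time)); A + B is the net
             kernel area, zero iff perfectly adapting.
    tau    : memory length (time), > 0.
    """

    alpha0: float
    beta: float
    A: float
    B: float
    tau: float
    strategy: str = "null"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        ok = {
            "adaptive": self.B > 0 and self.A == -self.B,
            "inverted": self.A > 0 and self.B == 0,
            "speculator": self.A > 0 and self.B < 0,
            "null": self.A == 0 and self.B == 0,
        }[self.strategy]
        if not ok:
            raise ValueError(
                f"(A={self.A}, B={self.B}) violates the {self.strategy} constraint"
            )

    def replace(self, **kw) -> "ResponseParams":
        return replace(self, **kw)


@dataclass
class KernelState:
    """Exponential memory integrals M1, M2 of the experienced concentration.

    For a constant past concentration c the fixed point is
    M1 = c*tau, M2 = c*tau**2.
    """

    M1: float
    M2: float


def kernel_value(params: ResponseParams, t) -> np.ndarray | float:
    """Response kernel R(t) = (A/tau + B t/tau^2) exp(-t/tau), t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("the kernel is causal: t must be >= 0")
    out = (params.A / params.tau + params.B * t / params.tau**2) * np.exp(-t / params.tau)
    return float(out) if out.ndim == 0 else out


def kernel_integral(params: ResponseParams) -> float:
    """Net kernel area int_0^inf R(s) ds = A + B (exact).

    Zero for the adaptive strategy: equal positive and negative lobes give
    perfect adaptation.
    """
    return params.A + params.B


def init_memory(params: ResponseParams, c_const: float) -> KernelState:
    """Steady-state memory as if the agent had sat at c_const forever."""
    if c_const < 0:
        raise ValueError("concentration must be >= 0")
    return KernelState(M1=c_const * params.tau, M2=c_const * params.tau**2)


def update_memory(state: KernelState, c: float, dt: float, tau: float) -> KernelState:
    """Advance both memory filters by dt with concentration held at c.

    Exact for piecewise-constant concentration: splitting the defining
    integrals at age dt gives
        M1' = e M1 + c tau (1 - e)
        M2' = e (M2 + dt M1) + c (tau^2 - e (tau^2 + tau dt))
    with e = exp(-dt/tau).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    e = np.exp(-dt / tau)
    return KernelState(
        M1=e * state.M1 + c * tau * (1.0 - e),
        M2=e * (state.M2 + dt * state.M1) + c * (tau**2 - e * (tau**2 + tau * dt)),
    )


def convolution_value(params: ResponseParams, state: KernelState) -> float:
    """int_0^inf R(s) c(t-s) ds = (A/tau) M1 + (B/tau^2) M2."""
    return params.A / params.tau * state.M1 + params.B / params.tau**2 * state.M2


def tumble_start_rate(params: ResponseParams, state: KernelState) -> float:
    """Clipped tumble-initiation rate max(0, alpha0 + int R c)."""
    return max(0.0, params.alpha0 + convolution_value(params, state))
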