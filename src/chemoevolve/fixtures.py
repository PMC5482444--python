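"""Deterministic synthetic fixtures for tests and the fitting workflow.

The published tumbling-probability measurements this model was matched to
(step responses of aerobically grown R. sphaeroides) are not shipped;
``synthetic_step_series`` generates a stand-in from stated response
parameters -- the exact forward model plus optional Gaussian noise -- and
``generate_fixture`` writes these, field snapshots and synthetic evolution
traces as CSV files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import TimeSeries, step_alpha_closed_form, tumble_probability
from .field import FieldParams, concentration, init_field
from .response import ResponseParams

__all__ = ["RSPH_FIT_PARAMS", "synthetic_step_series", "generate_fixture"]

# speculator parameters reported by the least-squares fit to the
# R. sphaeroides tumbling-probability trace (units: s and mM)
RSPH_FIT_PARAMS = ResponseParams(
    alpha0=0.074, beta=0.034, A=1300.0, B=-1000.0, tau=71.0, strategy="speculator"
)


def synthetic_step_series(
    params: ResponseParams = RSPH_FIT_PARAMS,
    c0: float = 1.0,
    t_on: float = 100.0,
    t_off: float = 400.0,
    t_end: float = 800.0,
    dt: float = 1.0,
    noise: float = 0.0,
    observable: str = "probability",
    seed=None,
) -> TimeSeries:
    """Synthetic tumbling series from the exact step response.

    ``noise`` is the Gaussian standard deviation expressed as a fraction of
    the series' peak value (e.g. 0.05 for 5%-of-peak noise).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + dt / 2.0, dt)
    alpha = step_alpha_closed_form(params, c0, t_on, t_off, t)
    y = tumble_probability(alpha, params.beta, t) if observable == "probability" else alpha
    if noise > 0:
        y = y + rng.normal(0.0, noise * float(np.max(y)), size=y.shape)
    return TimeSeries(
        t=t, y=y,
        meta={"observable": observable, "c0": c0, "t_on": t_on, "t_off": t_off},
    )


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0, out_dir=".") -> Path:
    """Write a deterministic CSV fixture; returns the file path.

    kinds: "step-series" (t, value tumbling trace), "field-snapshot"
    (x, c on a 1000-point grid of an equilibrated field), "trace"
    (a 700-generation synthetic fitness plateau in evolution-trace form).
    """
    params = dict(params or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if kind == "step-series":
        noise = params.pop("noise", 0.05)
        series = synthetic_step_series(noise=noise, seed=seed, **params)
        path = out_dir / f"step_series_seed{seed}.csv"
        df = pd.DataFrame({"t": series.t, "value": series.y})
        header = (
            f"# synthetic tumbling-{series.meta['observable']} step series; "
            f"t in s, value dimensionless; seed={seed}\n"
        )
    elif kind == "field-snapshot":
        T = params.get("T", 1e3)
        L = params.get("L", 20.0)
        fp = FieldParams(T=T, L=L, ell=params.get("ell", 100.0))
        state = init_field(fp, seed)
        x = np.linspace(0.0, fp.ell, 1000, endpoint=False)
        path = out_dir / f"field_snapshot_T{T:g}_L{L:g}_seed{seed}.csv"
        df = pd.DataFrame({"x": x, "c": concentration(state, fp, x)})
        header = f"# equilibrated field snapshot, T={T:g} L={L:g}; x, c in simulation units\n"
    elif kind == "trace":
        n = params.get("n_generations", 700)
        rng = np.random.default_rng(seed)
        F = 1.0 + rng.normal(0.0, 1e-3, size=n)  # noisy plateau
        df = pd.DataFrame(
            {
                "generation": np.arange(1, n + 1),
                "mutated": "tau",
                "alpha0": 0.01, "beta": 0.1, "A": 50.0, "B": -45.0, "tau": 40.0,
                "F_w": F, "F_m": F, "accepted": False, "F_chain": F,
            }
        )
        path = out_dir / f"trace_plateau_seed{seed}.csv"
        header = "# synthetic evolution trace: fitness plateau; times in simulation units\n"
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path
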