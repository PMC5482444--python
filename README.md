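# chemoevolve

Run-and-tumble bacterial chemotaxis in stochastic attractant fields, with
evolutionary optimization of the chemotactic response.

## The problem

*Escherichia coli* finds food by biasing a random walk: it runs in straight
lines, occasionally tumbles to reorient, and lowers its tumbling rate when
life is improving — the perfectly adapting response. But many bacteria do
the apparent opposite, tumbling *more* in the presence of attractant
(aerobically grown *Rhodobacter sphaeroides*, various aerotaxis and redox
mutants). Under what environmental conditions is such a seemingly
paradoxical strategy a good one?

`chemoevolve` is a simulation laboratory for that question. A single
bacterium lives on a periodic 1D world of length ℓ = 100 whose attractant
concentration is a stochastic spectral field with tunable correlation time
T and correlation length L. Its tumble-initiation rate is a clipped linear
response to the concentration history it has experienced,

    α(t) = max(0, α₀ + ∫₀^∞ R(s) c(x_B(t−s), t−s) ds),
    R(s) = (A/τ + B s/τ²) e^{−s/τ},

while the tumble-stop rate β is constant. Sign constraints on the kernel
amplitudes define three strategies:

| strategy   | constraint        | behavior |
|------------|-------------------|----------|
| adaptive   | A = −B < 0        | perfectly adapting hill climber (the *E. coli* response) |
| inverted   | A > 0, B = 0      | tumbles more at high absolute concentration |
| speculator | A > 0 > B         | compares the recent past to a long-term average; tumbles persistently when conditions beat the average, swims off when they decline |

Fitness is the inverse time to experience a fixed amount of attractant,
F = T⟨1/D⟩ over replicate field realizations, and a Metropolis–Hastings
chain (temperature U = 0.005, log-scale mutations) optimizes
(α₀, β, A, B, τ) under each strategy's constraint against a
non-chemotaxing baseline.

## What is in the package

- `chemoevolve.field` — the spectral attractant field (Fourier modes with
  AR(1)/Ornstein–Uhlenbeck weights, variance 1/p\* per mode, p\* = ℓ/L), a
  static isotropic 3D analogue, and deterministic test environments
  (concentration steps, two antiphase oscillating Gaussian peaks).
- `chemoevolve.response` — the kernel, and an exact O(1) two-filter
  recursion for the response convolution (no stored history).
- `chemoevolve.agent` — the two-state (run/tumble) Monte Carlo stepper,
  with a numba-compiled engine and a pure-Python reference engine that
  consume identical random streams.
- `chemoevolve.fitness` — F = T⟨1/D⟩, paired wild-type/mutant evaluation
  on common random fields, relative fitness against the baseline.
- `chemoevolve.evolve` — the Metropolis–Hastings chain, convergence
  detection, and final-window parameter summaries.
- `chemoevolve.experiments` — step-response time courses, least-squares
  recovery of the five response parameters from a tumbling-probability
  trace, the two-Gaussian tracking experiment, and 3D-traversal
  autocorrelation.
- `chemoevolve` CLI — `simulate`, `fitness`, `evolve`, `step-response`,
  `fit`, `two-gaussian`, `field-stats`, `experiment-3d`, `fixtures`.

## Worked example

```python
import numpy as np
import chemoevolve as ce

speculator = ce.ResponseParams(alpha0=0.0089, beta=0.056, A=74.0, B=-67.0,
                               tau=33.0, strategy="speculator")

# deterministic step response: attractant 0 -> 1 at t = 50, removed at 350
ts = ce.step_response_timecourse(speculator, c0=1.0, t_on=50.0, t_off=350.0,
                                 t_end=600.0)
for t_query in (40.0, 300.0, 360.0):
    k = int(np.searchsorted(ts.t, t_query))
    print(f"alpha({t_query:.0f}) = {ts.y[k]:.4f}")

# fitness against the non-chemotaxing baseline in a stochastic field
rel = ce.relative_fitness(speculator, T=1e3, L=20.0, field_seeds=np.arange(10),
                          agent_rng=0, stop_factor=5.0, t_max_factor=100.0)
print(f"relative fitness vs non-chemotaxing baseline: {rel:.2f}")
```

prints

```
alpha(40) = 0.0089
alpha(300) = 7.2714
alpha(360) = 0.0000
relative fitness vs non-chemotaxing baseline: 2.94
```

Before the step the rate sits at its basal value α₀. Under sustained
attractant it settles near α₀ + c·(A+B) ≈ 7: the speculator does *not*
adapt — it tumbles persistently while conditions beat its long-term
average. When attractant is removed the rate clips to zero and the
bacterium swims away in search of better conditions. In a slowly varying
(T = 10³), many-peaked (L = 20) stochastic world this strategy collects
attractant about three times faster than a non-chemotaxing bacterium.

An evolutionary run at reduced (desk) scale:

```sh
chemoevolve evolve --strategy speculator --T 1000 --L 50 --scale desk \
    --generations 3000 --seed 1 --out trace.csv
```

writes the per-generation trace and prints final-window parameter means.
Full convergence of these chains is an hour-scale computation on one core.

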