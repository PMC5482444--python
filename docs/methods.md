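# Methods

## Model

A single bacterium moves on a periodic 1D interval of length ℓ = 100 at
speed v = 1 when running, and is stationary when tumbling. Transitions are
a two-state Markov process: running → tumbling at rate α(t), tumbling →
running at constant rate β, resuming left or right with equal probability.
The tumble-initiation rate is a clipped linear response to the experienced
attractant history,

    α(t) = max(0, α₀ + ∫₀^∞ R(s) c(x_B(t−s), t−s) ds),
    R(s) = (A/τ + B s/τ²) e^{−s/τ}.

∫₀^∞ R = A + B is the net kernel area; A + B = 0 (the adaptive constraint
A = −B) gives perfect adaptation: the steady-state rate under any constant
concentration is exactly α₀. The inverted strategy (A > 0, B = 0) responds
to absolute concentration; the speculator strategy (A > 0 > B, |B| < |A|)
compares the recent past against a τ-scale running average and does not
adapt. The non-chemotaxing baseline is A = B = 0 with α₀ = 0 (an
always-running agent).

## Stochastic attractant field

c(x, t) = max(0, Σ_{p=1}^{p*} X_p(t) cos(2πpx/ℓ) + Y_p(t) sin(2πpx/ℓ)),
with p\* = ℓ/L (rounded to an integer ≥ 1, with a warning if ℓ/L is not
integral). Each weight follows the AR(1) update, every Δt_c = T/100,

    X_p ← X_p (1 − Δt_c/T) + η √(2Δt_c/(T p*)),  η ~ N(0,1),

independently per mode and per weight. Stationary weight variance is
1/(p\*(1 − Δt_c/(2T))) ≈ 1/p\*, so the unclipped field has unit variance at
every point and the clipped field has mean 1/√(2π) ≈ 0.399 independent of
T and L — which is what makes the baseline fitness independent of the
field parameters. Temporal weight autocorrelation decays with time
constant T; spatial covariance of the unclipped field is
(1/p\*) Σ_p cos(2πpd/ℓ). Fields are initialized at zero weights and
equilibrated for 2T (the update rule's stationarity transient) before the
agent is released; the field is held constant between updates.

The 3D analogue is static: weights X_pqr, Y_pqr for mode triples
p, q, r ∈ {1..p\*} drawn i.i.d. N(0, 1/p\*³), multiplying
cos/sin(2π(px+qy+rz)/ℓ). The per-weight variance is chosen so the
covariance along each coordinate axis equals the 1D closed form. The
field is real by construction (cosine and sine parts with independent
real weights); 3D values are not clipped for the traversal experiment,
since clipping is irrelevant to a correlation-length comparison (a clipped
variant is available via a flag).

## Agent stepping

The agent state updates every Δt_B = min(T, L/v, τ/20). Per step, in
order: read c at the current position; advance the response memory;
compute α; attempt one mode switch (running → tumbling with probability
1 − e^{−αΔt_B}, tumbling → running with 1 − e^{−βΔt_B}); move if running;
accumulate c·Δt_B; advance the clock. The exponential switching form is
exact for a constant rate within the step and safe for large αΔt_B. A run
ends when the accumulated attractant crosses `stop_factor · T` (50T at
full scale); the crossing time D is the step-end time (error ≤ Δt_B ≪ D).
A safety cap t_max = `t_max_factor · T` guarantees termination; truncated
runs contribute the lower bound 1/t_max to the fitness mean and are
counted (an evaluation with every replicate truncated raises an error).

The kernel-free baseline has no τ scale; it steps at min(T, L/v)/20. The
plain min(T, L/v) can equal ℓ, in which case the moving agent aliases the
field (it samples the same position each step) and the baseline fitness
acquires a spurious L dependence.

The response convolution is evaluated by an exact recursion on two
exponentially weighted memories, M1 = ∫ e^{−s/τ} c ds and
M2 = ∫ s e^{−s/τ} c ds, with ∫Rc = (A/τ)M1 + (B/τ²)M2. Splitting the
integrals at age Δt gives, for c constant over the step,

    M1' = e M1 + cτ(1−e),   M2' = e (M2 + Δt·M1) + c(τ² − e(τ² + τΔt)),

with e = e^{−Δt/τ}. This is exact for the piecewise-constant concentration
the simulation produces (verified against direct quadrature to 1e−9) and
O(1) per step. Memory is initialized at the steady state of the agent's
starting concentration (M1 = cτ, M2 = cτ²), representing an agent
equilibrated to its release point.

Two engines share this scheme: a numba-compiled chunked loop (default) and
a pure-Python reference stepper. Both consume the same random streams —
field noise from a per-realization generator keyed by the field seed,
agent uniforms from a separate generator — and agree step for step. In
the compiled engine the per-mode cos/sin phases advance by rotation
recurrences (recomputed from the position at every chunk entry, bounding
roundoff drift), and time is computed as step-count × Δt_B rather than
accumulated, so field-update scheduling cannot drift.

## Fitness and pairing

F = T·mean(1/D_i) over replicate field seeds. Wild type and mutant are
evaluated on the same seeds — each seed regenerates bit-identical field
dynamics regardless of the agent parameters — so environmental luck
cancels in the comparison; agent-level randomness is fresh per run.
Relative fitness divides by the baseline's F on the same seeds, replaying
the same agent stream for both, making the ratio a deterministic function
of the seeds (and exactly 1 for the baseline itself).

## Evolutionary optimization

One generation = mutate, evaluate both genotypes on fresh common fields,
accept with the Metropolis rule (p = 1 if F_m ≥ F_w, else
e^{(F_m−F_w)/(U F_w)}, U = 0.005). One parameter is mutated per
generation, chosen uniformly among the strategy's mutable set (adaptive
mutates B only, A is slaved to −B), on a log scale:
|a| → exp(ln|a| + r), r ~ U(−0.2, 0.2), sign preserved. Initialization is
U(0, 1) per parameter (adaptive B ~ U(1, 10) at T ≥ 10⁴; speculator
B ~ U(−1, 0)).

Magnitude floors are enforced by redrawing r (budget 100, then the parent
value is kept): α₀ > 10⁻³ (adaptive, inverted), A and |B| > e⁻¹
(speculator), τ > 0.01 (adaptive), and β > 10⁻⁶ everywhere for numerical
safety. Because initialization can legitimately start below a floor, a
proposal is rejected only if it is below the floor *and* moves away from
it; chains below a floor can therefore climb back but never sink further.

Convergence: the chain stops when no fitness in the last `window` (600)
generations exceeds the window-start fitness by more than 1% relative —
the plateau criterion made concrete for a stochastic fitness. Because the
window-start value is itself a noisy sample, a window that happens to open
on an upward fitness spike can fire the detector mid-climb when the
per-generation fitness noise is large (tens of percent at the desk
preset); treat desk-scale "converged" flags accordingly. Summaries
are arithmetic means of the post-selection chain state over the final
window (per parameter, plus B/A and fitness).

Scale presets. The full-scale protocol (10 replicates, 50T threshold,
600-generation window, unbounded generations) is an hour-scale-or-more
computation per chain on one core. The `desk` preset — 5 replicates, 5T
threshold, t_max = 100T, ≤ 3000 generations — is a first-class reduced
configuration. It additionally floors τ at 0.05 (adaptive) / 0.1
(inverted, speculator), applied at initialization and mutation: the agent
step is τ/20, so simulation cost grows as 1/τ and an early-chain excursion
to τ ≈ 0.01 makes single generations minute-scale. These floors sit well
below every published optimum at the conditions studied here (adaptive τ
0.072–0.27, inverted 5.6–8.3, speculator 39–45) and are a tractability
device in the same spirit as the model's own parameter floors. Even under
the desk preset, chains starting from U(0,1) genotypes have a weak
selection signal relative to the 5-replicate fitness noise, and traversing
the ~6 nats of log-parameter space to a strategy's optimum is a
multi-thousand-generation affair; the capped evolution run in the
acceptance tests (60 generations per strategy) exercises the machinery but
is not expected to reach the optima.

## Experiments

**Step responses.** A spatially uniform step drives the memory recursion
deterministically (no motion). The closed form
α(t) = max(0, α₀ + c₀[A(1−e^{−t̂/τ}) + B(1−(1+t̂/τ)e^{−t̂/τ})]), with
superposed opposite step at removal, serves as an oracle; recursion and
closed form agree to 1e−9.

**Kernel fit.** The observable of a tumbling-probability trace is modeled
as the occupancy of the two-state system driven by α(t): the master
equation dp/dt = α(t)(1−p) − βp, integrated exactly for α piecewise
constant between samples. The quasi-steady occupancy α/(α+β) is *not*
used: it is exactly invariant under a common rescaling of
(α₀, β, A, B), so the absolute rate scale would be unidentifiable; the
master equation's relaxation lag ~1/(α+β) breaks that degeneracy, and
noiseless recovery of all five parameters is then exact. Fits run in log
space (B through its magnitude, preserving the speculator signs) with
multiple restarts. A raw-rate observable is available (`observable="rate"`),
in which β does not appear. Identifiability caveat: for reference
parameters with A+B ≫ β the occupancy saturates near 1 under sustained
attractant, exponentially suppressing amplitude information; with
5%-of-peak noise the likelihood surface for A, B, τ is tens of percent
wide (measured by fitting from the true parameters), so noisy recovery of
the amplitudes to 10% is not achievable for the reference parameter set —
α₀ and β still recover to a few percent.

**Two-Gaussian world.** Two Gaussian bumps (σ = 3) at x = 25 and 75
oscillate in antiphase with period 5000: A₁(θ) = (1+cos(2πθ/5000))/2,
A₂ = 1 − A₁ (the published description fixes only antiphase, range [0,1]
and the period; the cosine waveform is our choice, making both amplitudes
1/2 at quarter period). Agents are simulated for one burn-in period plus
the measured periods, positions are folded by phase and summarized with
circular statistics (the world is periodic). The "departure phase" is the
first θ at which the population's circular mean is closer to the growing
peak than to the declining one.

**3D traversal.** A walker crosses the static 3D field in straight runs
of length 2ℓ with random isotropic re-orientation between runs, sampling
every v·dt. The experienced-concentration ACF (mean-removed, biased
normalization) reproduces the 1D field's main lobe and 1/e correlation
length. The 1D spectrum's negative side lobes do not survive in 3D: along
an oblique direction the projected mode frequencies p·n̂ spread
continuously and the lobes decohere. This is a geometric property of any
isotropic grid-mode construction, so the comparison asserted in tests is
main-lobe agreement and the effective correlation length — the property
the traversal experiment is meant to establish.

## Synthetic data

The tumbling-probability step series consumed by the fit demonstrations is
generated by the package's own forward model from stated parameters
(optionally with Gaussian noise, parameterized as a fraction of the series
peak), as a synthetic stand-in for digitized experimental traces, which
are not shipped. Passing fit tests therefore demonstrate recovery under
the model's own assumptions (linear response, two-state switching,
piecewise-constant sampling); they do not validate the model against real
measurements, receptor saturation, or non-stationary baselines.

## Numerical choices and problem sizes

- All randomness flows through numpy Generators; every simulation is
  reproducible from (field seed, agent seed), every chain from its config
  seed. Field seeds are drawn below 2³¹.
- Clipping max(0, ·) is applied at field evaluation and at the rate; the
  linearity of the convolution holds before clipping.
- Test problem sizes: field statistics use 10⁵ AR(1) updates (correlation
  time recovered within 10%) and 2000–3000 snapshots one correlation time
  apart for spatial covariance (Monte Carlo band ±0.12); the convolution
  oracle uses 100 random histories against adaptive quadrature; kernel
  fits sample 0–900 s at Δt = 0.25; the tracking experiment uses 50 agents
  × 2 measured periods; the traversal uses 200 runs of length 2ℓ × 3 field
  realizations; the in-suite evolution runs 60 generations per strategy at
  the desk preset.
- Known limitations: no 2D/3D agent dynamics (the traversal experiment is
  a straight-line probe), no receptor saturation or adaptation-mechanism
  biochemistry, no motility energy costs, single-lineage optimization
  (no population dynamics), and the desk-scale evolution documented above.
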