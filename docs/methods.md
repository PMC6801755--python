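# Methods

## Model and assumptions

The package implements a renewal description of kinesin stepping.  The
dimer alternates between a two-head-bound state and a one-head-bound
intermediate (INT).  ATPase activity (hydrolysis + Pi release, treated as
one irreversible rate-limiting transition at saturating ATP) fires at
`k_plus` in the trailing head and `k_minus` in the leading head.  The
central assumption is that these rate constants depend on neck-linker
*orientation* only — not on external force and not on neck-linker length
or strain — so the total ATPase rate during processive stepping is the
constant `k_plus + k_minus` at every load.  Force enters exclusively
through two branch probabilities:

* `P0`, the probability that the freshly produced ADP-head escapes its
  transiently weakened binding site.  Wild-type dimers carry ~30 pN of
  internal neck-linker tension and escape with certainty (`P0 = 1`).
  Extended-neck-linker mutants have near-zero internal tension and
  `P0(0) < 1`; load on the *loaded* head raises it as
  `P0(F) = 1 − [1 − P0(0)] exp(−|F| δ / kBT)` with `δ = 1 nm`
  (a Debye-length scale).  A backward force loads only the leading head,
  a forward force only the trailing head; the unloaded side keeps
  `P0(0)`.
* `PE = ρ/(ρ + k_plus/k_minus)` with `ρ = r0^(1−F/FS)`, the probability
  that the detached head rebinds forward rather than backward out of
  INT.  The backward barrier includes the neck-linker docking energy
  `ED`, giving the zero-force ratio `r0 = (k_plus/k_minus) exp(ED/kBT)`;
  inverting this is how `nl_docking_energy` works.

Everything observable follows in closed form (module `analytic`):
stepping ratio, velocity, dwell time, diffusion constant, randomness
`R = 2D/(vd)`, ATP per (forward) step, power `W = vF/kBT` and efficiency
`η = W/[(k_plus+k_minus)ΔG]`.  With `P0 = 1` every expression reduces to
the wild-type form; this reduction is enforced by tests at machine
precision.

A deliberate reading decision: the plain-text stepping-ratio expression
is interpreted as `r0` raised to the power `(1 − F/FS)` (equivalently
`r0·exp(−βd⁺F)` with `FS = kBT·ln r0 / d⁺`).  This interpretation
reproduces the seven published maximum-power values to <0.4% and is the
backbone of every force dependence in the package.

## Parameters

| field | meaning | units | default |
|---|---|---|---|
| `r0` | stepping ratio at F = 0 | – | per species |
| `FS` | stall-force scale (`= ln r0 · kBT/d⁺`) | pN | per species |
| `k_plus`, `k_minus` | trailing/leading ATPase rates | s⁻¹ | per species |
| `P0_zero` | escape probability at F = 0 | – | 1 (wild type) |
| `kb` | second-order ATP binding | µM⁻¹s⁻¹ | 3.3 |
| `k_off_leading` | ATP dissociation, leading head | s⁻¹ | 30 |
| `k_off_other` | ATP dissociation elsewhere | s⁻¹ | 0 |
| `delta` | force scale of `P0(F)` | nm | 1 |
| `d` | step size (microtubule period) | nm | 8.2 |
| `T` | temperature | K | 298 |

`kBT` is computed as `0.0138065 pN·nm/K × T` (4.114 pN·nm at 298 K).
The nucleotide constants `kb`/`k_off_leading` were calibrated only for
the motors studied at low ATP (HsK-CL-6AA, KIF17); the other presets
carry the same values as an explicit extrapolation so any preset can be
simulated at finite ATP.  Published 1σ uncertainties are stored on the
presets and used only where asked for (docking-energy error propagation,
first order in Δr0/r0 + Δk⁻/k⁻ + Δk⁺/k⁺).

`ΔG = 20 kBT` per ATP (physiological) is the efficiency default.

## Stochastic engines

Two engines simulate the identical Markov state machine (module `mc`):
an event-driven scheme with exponential waiting times (`exact_trace`,
the reference and the default for ensembles) and a fixed-timestep scheme
(`simulate_trace`) in which each candidate transition of each head draws
one uniform variate per step, at most one chemical transition per head
per step.  The classic timestep is 1e-4 s; because the stability
condition `rate·Δt < 0.01` must hold for every active rate, the default
`dt=None` auto-selects the largest step ≤ 1e-4 s that satisfies it, and
an explicitly supplied unstable `dt` raises an error pointing to the
exact engine.  Cross-validation tests hold the two engines to agreement
within 3 combined SEM at saturating and at 20 µM ATP, and halving the
timestep moves ensemble means by less than 3 combined SEM (two finite
ensembles from the *same* distribution differ by ~1.4 SEM on average, so
a 1-SEM bound would be uninformative).

Zero-duration cascades (detach → dock → rebind, all "immediate" in the
model) are logged as separate events sharing one timestamp in causal
order, so event times are non-decreasing rather than strictly
increasing.  At the saturating-ATP sentinel (`atp = inf`), ATP binding
is instantaneous and unlogged, and the leading-head dissociation channel
is skipped (dissociation followed by instant rebinding is a no-op).
The logged centre-of-mass coordinate changes only at rebind events, by
±d or 0.

Seeding: trace `i` of an ensemble uses `base_seed + i (mod 2^31)`;
identical seeds give bit-identical traces.

## Trace analysis

`bead_position_series` reproduces the optical-trap measurement
convention under backward load: only moves between INT and the *front*
binding site displace the bead (−d on front-head detachment, +d on
forward or front-returning rebinding); rear-head excursions are
invisible.  For F ≤ 0 the centre-of-mass record is used — the convention
the closed forms are written in — with the switch at F = 0.  Sampling
defaults to 2 kHz.  `detect_steps` counts a level change only if the new
level persists beyond 0.5 ms, absorbing shorter excursions into the
preceding level; a retained jump of m·d counts as m steps.  At
saturating ATP the INT dwell is instantaneous and bead-counted and
centre-of-mass step ratios agree (tested at 10%, the residual being
finite-sampling losses of rapid opposite-direction pairs).

`summarize` reduces an ensemble to experiment-like numbers: velocity
from per-trace end-to-end displacement past a 1% burn-in; stepping ratio
and ATP-per-step from pooled event counts (delta-method SEMs on pooled
counts); the diffusion constant from the fitted slope of the
across-trace position variance over the second half of the run (the
window suppresses initial-condition transients; the estimate is
insensitive to it within its SEM); randomness as `2D/(vd)`.

## Fitting

`fit_force_velocity` minimizes `Σ[(v_model − v_i)/σ_i]²` (σ = 1 where
absent) with `scipy.optimize.least_squares` under bounds
(r0 ∈ (1, 1e5), FS ∈ (0.5, 20) pN, rates ∈ (0.1, 1e4) s⁻¹,
P0_zero ∈ (0.01, 1]), from 5 jittered starts because `r0` and `FS`
couple through `ln(r0)/FS`.  Joint fits share the four kinetic constants
across datasets; datasets flagged wild-type pin `P0_zero = 1` while the
mutant datasets share the free escape probability.  Standard errors are
Jacobian-covariance scaled by `RSS/(n − p)` — one defensible convention,
stated as such.  `fit_stepping_ratio` fits on `ln r`, where the
wild-type model is exactly linear in force.

The synthetic generator applies multiplicative Gaussian noise,
`v_i = v_model(F_i)(1 + ε_i)`, `ε_i ~ N(0, cv²)`, and records
`σ_i = |v_model|·cv`.  It emulates the scatter of optical-trap
force–velocity points but none of the instrument systematics (trap
compliance, drift, bead-linkage filtering), so recovery tests
demonstrate estimator correctness and statistical power, not robustness
to real-world artefacts.

Identifiability, measured at the standard study design (15 forces in
[−5, 7.5] pN, 2% noise) by the Cramér–Rao bound: FS and k⁺ are sharp
(0.3%, 0.8%); r0 and k⁻ are soft (15%, 8%) and anticorrelated (−0.96)
because the data constrain mainly their product through
`r0·k⁻/k⁺ = exp(ED/kBT)`.  Estimates are unbiased (200-replicate median
bias ≤ 1.5% on every constant), but single-replicate r0 values scatter
broadly — a property of the experiment design, not of the optimizer.

## Numerical choices

* Stall force: exactly `FS` for wild-type; otherwise the root of
  `v(F) = 0` bracketed on [0, FS] (Brent, xtol 1e-6 pN).
* Maximum power: bounded scalar minimization of −W on (0, stall),
  xatol 1e-10.
* Randomness at stall: a scalar query raises `StallDivergenceError`;
  array queries return NaN with a warning (scan tables show NaN there).
* Dwell-series identity: the independent check sums
  `n q (1−q)^(n−1)/(k⁺+k⁻)` adaptively until the geometric tail is below
  1e-14, since near stall the per-event step probability q is small and
  a fixed 200-term sum cannot reach 1e-9 relative accuracy.
* Degenerate inputs: `k_minus = 0` makes `PE = 1` (documented limit) and
  the docking energy undefined (error); `atp = 0` yields an inert motor.

## Problem sizes

Stochastic validation runs 1000 traces × 10 s per condition for the
preset × {0, 2, 4} pN grid, 200–500 traces for module-level checks, and
the Michaelis–Menten scan 400 traces × 10 s per concentration; recovery
studies use 50 replicates of 15-point datasets.  With the event-driven
engine a 1000-trace saturating ensemble takes a fraction of a second.

## Known limitations

* No temperature dependence of the rate constants: presets are 298 K
  calibrations, and `T` only rescales kBT.
* Constant step size d; measured ±2 nm step-size fluctuation is not
  modelled.
* No irreversible detachment/run-length termination, no trap compliance
  (force is constant, not position-dependent), no measurement noise on
  traces, no stalk-length/limping effects.
* Exactly at stall ensemble statistics are noisy (ratio SEMs blow up);
  validation grids stay ≥ 0.3 pN away from stall.
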