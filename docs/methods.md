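# Methods

## The model

`bsfopt` simulates the adult phase of a black soldier fly (*Hermetia
illucens*, BSF) breeding cage as a deterministic, continuous-population
ODE.  Only females are tracked: males mate multiply, so an uneven sex
ratio does not limit fertilization, and eggs are what the process sells.
Adults do not feed on solids; everything the fly does runs off reserves
accumulated as a larva, which is the central economy of the model.

Seven states evolve over a production cycle:

| state  | meaning                                        | unit  |
|--------|------------------------------------------------|-------|
| N_y    | young flies (pupae → hardened adults)          | count |
| N_act  | sexually active flies                          | count |
| N_fert | fertilized, egg-laying flies                   | count |
| N_old  | flies that completed oviposition               | count |
| T_sum  | accumulated development degree-days            | °C·d  |
| μ      | reserve-depletion ("dying-rate") state         | –     |
| m_e    | cumulative egg mass                            | mg    |

Two controls drive the cage: temperature `u_T` (°C) and photoperiod
`u_L` (light hours per day).

**Development.** `T_sum` integrates max(0, u_T − k_T_sum_min), a standard
degree-day clock with base temperature 12 °C.  Stage transitions are
gated by it: flies become sexually active once T_sum ≥ 28 °C·d and can
complete oviposition once T_sum ≥ 56 °C·d (the mating threshold is set to
half the preoviposition threshold).  Gates multiply first-order transfer
rates k_y2act = 0.28 d⁻¹, k_fert2old = 0.55 d⁻¹ and the egg-laying rate
k_ovi = 5.9 mg d⁻¹ per fertilized female.

**Mating.** The active→fertilized transfer is k_act2fert = 0.62 d⁻¹
scaled by the photoperiod response ξ_L(u_L) = a1·(1 − e^(−a2·u_L)): more
light hours raise the chance of finding a partner, saturating near 16 h/d.
This transfer deliberately carries no development gate — early mating is
impossible anyway because N_act stays empty until the mating gate opens.

**Reserves and death.** μ grows linearly at ξ_T,μ(u_T)·k_μ with
k_μ = 0.0183 d⁻¹ and a convex temperature factor (quadratic, vertex near
25 °C).  Negative μ means reserves remain; once μ crosses zero the flies
starve and die at rate k_mu_N·max(0, μ) (old flies faster, k_mu_old =
2.14 d⁻¹, reflecting the energetic cost of completed reproduction).  μ is
treated as dimensionless; the death-rate coefficients carry the d⁻¹.

**Egg production.** ṁ_e = (1 − k_mu_ovi·μ)·ξ_T,ovi(u_T)·f_ovi(T_sum)·N_fert.
The reserve factor (1 − 2.5μ) rewards well-fed flies (μ < 0 boosts
laying) and is deliberately not clipped: on the 14-d horizon with
admissible controls μ stays below 0.29, so the factor stays positive
(asserted in tests).  ξ_T,ovi is a concave quadratic peaking at 28.6 °C.
The fecundity polynomial may go negative outside 20–37 °C; a clipping
option exists for out-of-range exploration but is off by default because
the literal polynomial is what reproduces the published behaviour inside
the admissible box.

Transition terms cancel pairwise in the total population, so the
population only ever decreases, and only under starvation — both
properties are asserted to machine precision in the test suite.

## Numerics

The step gates and max(0, ·) terms are replaced by the smooth surrogate
½ + ½·tanh(k·x) (and x times it) with steepness k = 50 in inverse units
of the switched quantity.  At k = 50 the development gates open over
≈0.1 °C·d (minutes of warm time) and first-oviposition timing shifts by
well under 0.02 d against exact switches; the benchmark 14-d egg mass
differs from hard switching by 0.7%.  Exact switches remain available
(`NumericsConfig(hard_mode=True)`) and every structural test runs both.

Integration is one classical RK4 step per 1-h control interval — the
operational cadence of cage controllers and the natural grid for
piecewise-constant schedules.  Halving the step changes the benchmark
egg mass by < 0.1%; an adaptive LSODA integrator at rtol 1e−9 agrees with
the fixed-step result to < 0.05% and serves as the cross-check.  States
are not projected to nonnegativity; instead a smoothing-tolerance
invariant (no count below −1e−6·N_y0) is enforced after every run.

Event times (first oviposition, population halving, 5%-survival
longevity, 90%-egg-mass abort) are located by linear interpolation
between hourly samples.  Egg/cycle metrics use the 14-d production
horizon; die-off metrics (halving, 5% survival) need an extended run and
default to 40 d.

## Standard conditions

Simulations start from N_y = 50 young females (the cage size of the
survival dataset the model was tuned against), all other counts zero,
T_sum = 0, m_e = 0, and μ0 = −0.1.  μ0 is unmeasurable and is chosen so
that reserves remain at emergence, first deaths begin near day 7, and
μ(14 d) ≈ 0.15; `select_mu0` reports all three achieved values for any
candidate (with the literal parameter set, μ(14 d) = 0.167 and the μ = 0
crossing sits at 5.2 d — the conditions are approximated, not met
exactly).  The benchmark environment is constant 25 °C and 16 h/d.

## Optimal control

The control problem minimizes ∫₀^14d (−Q·m_e + ũᵀRũ) dt over hourly
piecewise-constant controls with box bounds 20–37 °C and 2–24 h/d,
Q = 12, R = 100·I.  Rewarding cumulative egg mass at every instant (not
just terminally) favours producing eggs *early*, which is what shortens
production cycles.

**Input scaling.**  The published objective is stated in raw physical
units, but with Q = 12 and R = 100 the raw-unit input term is ~20×
larger than the egg term and its optimum collapses onto the lower
bounds — contradicting both the declared intent that egg mass and inputs
carry "similar importance" and every reported optimization outcome.  The
package therefore normalizes inputs by the benchmark operating point
ũ = (u_T/25, u_L/16) by default.  This reading was validated against the
full set of published standard-scenario outcomes (sign and size of the
heating change, light reduction, abort-time shift, accumulated inputs);
the plausible alternative (normalizing by tens, ũ = u/10) fails that
comparison — it drives heating *below* the benchmark.  Raw units remain
available via `input_scale=None`.

**Transcription and solver.**  Single shooting: one RK4 step per control
interval, smooth switching (mandatory — gradients), running cost by the
rectangle rule on the same grid.  Gradients of the shooting map are exact
to machine precision via batched complex-step differentiation (all 672
perturbed rollouts propagate simultaneously as trailing array columns).
The bound-constrained NLP is solved by L-BFGS-B with a steepness
continuation: a first solve with the gates softened to k = 10, then a
refinement at the simulator steepness k = 50.  Without the continuation
the steep tanh gates corrugate the objective finely enough to defeat
quasi-Newton line searches at grid-dependent points; with it, optimized
egg mass agrees within 0.7% between 2-h and 1-h control grids.  The
initial guess is the benchmark constants, so solves are deterministic.

The oviposition-delay scenario adds the point constraint T_sum(6 d) ≤
56 °C·d (push the laying phase past a weekend).  Because this is a single
scalar constraint on the temperature history alone and is active at the
optimum, it is solved by bisection on its Lagrange multiplier with warm-
started L-BFGS-B inner solves at the softened steepness, keeping the best
feasible iterate, plus one fixed-multiplier polish at full steepness
(accepted only if still feasible).  SQP on the same transcription stalls
in its line search well short of this solution.

Reported scenario metrics are always recomputed by re-simulating the
returned schedule with the simulator defaults, never read off the
optimizer's internal model.

**Scenarios.**  `standard` (Q = 12, R = 100·I), `high_penalty`
(R = 1000·I), `light_only` (temperature frozen at 25 °C), `delayed`
(constraint above, reported with the one-third loss of eggs laid before
day 6).  Under the default scaling the standard scenario improves 14-d
egg mass by ≈ +11.7% over the benchmark (published: +9.4%) with the same
qualitative solution — light at the 2 h/d minimum while no flies are
active, temperature raised toward ≈28 °C; the residual gap traces back to
the cost-scaling ambiguity above.  The delayed scenario yields a ≈ +3%
harvestable gain (published +10.6%); the direction agrees, the size
depends on how many benchmark eggs fall before the day-6 cutoff, where
this model lays ~30% fewer than the published trajectories.

## Calibration

The fitting workflow runs entirely on synthetic observation sets with
embedded ground truth (module `synthetic`), in the same order the model
was originally identified: thresholds are taken as given; base
stage-transition rates are fitted to population and egg-mass series
recorded under neutral responses (ξ_T = ξ_L = 1, realized by a parameter
override rather than a special code path); the light curve and the
fecundity parabola are fitted directly (nonlinear least squares /
ordinary polynomial regression); and the mortality parabola is fitted
indirectly by matching simulated 5%-survival longevity to observed
longevity, because μ itself is unobservable.  In that indirect fit only
the product ξ_T,μ·k_μ is identifiable, so k_μ stays frozen.  Stage rates
are optimized in log space to keep them positive.

Noiseless recovery is exact to solver tolerance for the direct curve
fits, within 1% for the trajectory fit, and within 2% longevity mismatch
for the indirect mortality fit.  The generators default to relative
(multiplicative) normal noise, matching the heteroscedastic scatter of
count data; every draw is seeded.

### What the synthetic data do not show

The generators emulate the *structure* of the literature data (design
ranges, normalization, noise character), not their inter-study
heterogeneity: real datasets differ in larval diet, cage size, genetics
and liquid feed, which is precisely why the published parameters carry
large uncertainty.  Passing recovery tests therefore demonstrates the
estimation machinery is correct and well-conditioned on model-generated
data — not that the literature values are right.  Refitting against the
original external datasets is out of scope.

## Known limitations

- Continuous population averages: no individual-fly events, so "first
  fly dies" is proxied by the μ = 0 crossing (the ΣN = N_y0 − 1 crossing
  is reported alongside).
- Humidity, light spectrum/intensity, liquid-feed choice, fertility and
  hatchability are outside the model; male flies are not tracked.
- The printed mortality coefficients put the longevity optimum at
  ≈25.2 °C; the study's figure text says 24 °C (and "longest at 22 °C"
  for halving time).  The package implements the printed coefficients
  literally, so longevity-vs-temperature monotonicity only holds above
  ≈25.5 °C.
- Local optimization only: solutions are deterministic local optima of a
  nonconvex program, with no global guarantee.
- Q and R are abstract weights; an economic parameterization (energy
  prices, egg value) is future work in the source study as well.
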