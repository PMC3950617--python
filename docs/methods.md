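# Methods

## The model

Patient flow is modelled as two queues in tandem with blocking after
service.  The ED is an M/G/c₁/∞ queue with K = 5 preemptive-resume
priority classes mapped from CTAS acuity levels; class 1 (CTAS I,
resuscitation) preempts, and a preempted treatment later resumes with its
remaining work intact.  The IU is a G/GI/c₂/c₂ loss system: an admission
finding all c₂ beds busy is lost if it arrived directly, and boards in its
ED bed if it is an ED transfer.  Boarding is folded into the ED service
time: with blocking probability P_b and expected time to the next
inpatient discharge E[min Tᵢ], the effective mean ED service time is

    1/μ = 1/μ₁ + P_b · E[min Tᵢ],

which couples the two queues because P_b itself depends on the transfer
rate x·min{λ, c₁μ}.  All internal computation is in hours; loaders convert
day-denominated stay distributions at the boundary.

Assumptions inherited from the model class: Poisson arrivals at long-run
average rates (no within-day profile), iid triangular service and stay
times, a single pooled IU accepting every patient type, one patient per
bed, and no abandonment.

## Parameters

| parameter | meaning | unit | baseline |
|---|---|---|---|
| λ₁…λ₅ | arrivals per CTAS level | 1/h | 0.075, 0.662, 3.749, 2.86, 0.226 |
| λ_d | direct IU admissions | 1/h | 0.267 |
| x | admitted fraction of ED patients | — | 0.479/7.572 ≈ 0.0633 |
| ED service | triangular(lower, mode, upper) | h | (0.1, 0.5, 1.0) |
| IU stay | triangular(lower, mode, upper) | h | (24, 96, 168) |
| c₁, c₂ | ED / IU beds | — | 20 / 125 |
| targets | max wait to physician per level | min | 3, 15, 30, 60, 120 |

The CTAS level-I target ("immediate") is operationalised as 3 minutes.
The transfer fraction is stored in the scenario file as the measured ED→IU
rate (0.479/h) and derived against the ED total so the two printed rates
stay mutually consistent.

## Waiting-time chain and the two metrics

The per-class c₁-server estimate composes four classical pieces:
Pollaczek–Khinchine (W₁ᶠ), the two-moment M/G/c system-time approximation
driven by Erlang-C (W_{c₁}ᶠ), the exact preemptive-resume M/G/1 per-class
formula (W₁ᵏ, with R_k = ½Σ_{i≤k} λᵢS̄ᵢ²), and the multi-server ratio
W_{c₁}ᵏ ≈ W_{c₁}ᶠ·W₁ᵏ/W₁ᶠ.  Two deliberate choices:

* **Reference-system scaling.**  The single-server quantities are
  evaluated with every class rate divided by c₁ (option `scaled`,
  default), which preserves the class mix and per-server load and keeps
  the reference M/G/1 stable whenever the c₁-server system is.  The
  `unscaled` option evaluates them at the raw rates and raises when that
  reference queue would be unstable (λS ≥ 1 — the case for any busy
  multi-server ED).
* **Metric duality.**  The M/M/1 and M/M/2 reductions of W_{c₁}ᶠ and W₁ᵏ
  are *sojourn times*, while W₁ᶠ is a *queueing delay*; the composed
  quantity is therefore system-time-like.  Results carry both
  `system_time` (faithful to the composition) and
  `queueing_delay = max(0, system_time − S̄ₖ)`; the planner compares
  `queueing_delay` to the CTAS targets ("time to physician") by default,
  switchable per scenario.

Degenerate cases bypass the heuristic ratio: c₁ = 1 returns the exact
single-server priority formula, K = 1 the FCFS estimate, zero traffic the
bare service times.

**Known bias.**  Because the composition divides sojourn-like quantities
by a pure delay, it *overestimates* per-class waits by a factor that grows
with c₁ at light load, and the composed waits are not monotone in bed
counts or arrival rates even though every building block is.  The
discrete-event simulator quantifies this: at the baseline arrival mix with
6 ED beds (ρ ≈ 0.67) the aggregate system time agrees within ~15%
(0.686 h analytic vs ~0.59 h simulated), but per-class delays are
over-predicted several-fold for the low-acuity classes.  Capacity answers
derived from the chain are therefore conservative (they over-provide
rather than under-provide), and comparisons should prefer aggregate
system time, which tracks the simulator well.  `edq compare` prints the
full side-by-side table.

## IU blocking

P_b uses a diffusion-style formula in β = √c₂(1−ρ_d), the stay SCV
(v = (1+C_a²)/2) and the Mills-ratio factor
α = [1+βΦ(β)/φ(β)]⁻¹.  Numerical handling:

* β → 0 is a 0/0 form; |β| < 10⁻⁶ switches to the analytic limit
  α·v/(c₂ρ_d).
* β < 0 (overloaded IU) is evaluated through `expm1` to avoid overflow,
  flagged in diagnostics, and the result clamped to [0, 1] (the fixed-point
  existence argument assumes P_b ∈ [0, 1]).
* Zero IU traffic returns P_b = 0 by definition.

The formula is asymptotic in c₂ and is used in the regime the model is
built for (c₂ ≳ 50, moderate occupancy).  Outside it the formula degrades
in two documented ways: it lies far below the exact Erlang-B value for
M/M/c₂/c₂ systems at mid-range c₂, and for c₂ ≲ 3 it diverges as
ρ_d → 0 (the clamp then yields P_b = 1 at negligible load).  The exact
Erlang-B recurrence ships alongside as the classical oracle, and the
simulator — which implements the physical loss system — matches Erlang-B
to within Monte-Carlo error.

The SCV entering v is that of the IU stay time (0.09375 for the baseline
triangular), and μ in ρ_d is the IU discharge rate 1/E[stay]; both
readings follow the loss-system context in which the formula is applied.

## Boarding delay

E[min Tᵢ] is computed as L + ∫(1−F)^{c₂} dz by adaptive quadrature
(absolute tolerance 10⁻⁸ h, split at the mode).  Tᵢ is modelled as a full
stay-time draw per occupied bed; the alternative reading — the stationary
residual of the stay at a random inspection epoch — is available behind
`residual=True` / `Scenario.residual_los`, but is off by default because
the boarding delay is defined by the stay-time CDF directly.  The choice
matters: the residual transform has support down to zero and yields a
smaller minimum.

## Fixed point

Two independent routes, cross-validated in the tests:

* **Root enumeration** (`find_mu_roots`): the residual
  1/μ − P_b(μ)·E[min Tᵢ] − 1/μ₁ is evaluated on a 512-point uniform grid
  over the provable bracket [μ_min, μ_max] (vectorised), every
  sign-change bracket is polished by Brent's method to |residual| < 10⁻¹⁰ h,
  and near-zero grid points are accepted directly.  Multiple roots are
  all reported; feasibility verdicts use the smallest root for the
  sufficient condition and the largest for the necessary one, and a
  necessary-and-sufficient condition exists when they coincide.
* **Moment iteration** (`solve`): starting from P_b = 0, alternate the
  blocking-modified class moments
  (S̄ₖ = Sₖ + P_b·E[min Tᵢ]; the second moment treats the boarding term
  as a deterministic shift, as the model defines it), the aggregate rate
  1/μ = Σ qₖS̄ₖ, and the new P_b, until the induced change in every
  modified mean is below 10⁻⁸ h.  The blocking knee can be steep enough
  that plain iteration 2-cycles; damped retries (0.5, then 0.9) and, as a
  guaranteed fallback, bisection on g(p) = P_b(μ(p)) − p (which brackets a
  root on [0, 1] by construction) make the solve converge on every regime
  the fixture generator produces.

Reported waits always use the moment-iteration fixed point; when several
roots exist the feasibility report is anchored on the smallest
(conservative) one.  `status` distinguishes `ok`, `unstable`
(λ ≥ c₁μ̂ — waits undefined) and `no_solution` (iteration failure —
never observed after the bisection fallback, but reported rather than
silently patched).

## Fast track

The split sends CTAS IV–V to an express line on
round-half-away-from-zero(fraction·c₁) beds (clamped to leave each line at
least one bed) and CTAS I–III to the remainder.  Both lines share one IU:
the joint fixed point iterates both lines' moments against a single P_b
driven by the summed transfer flow.  Two modelling choices at
under-determined points:

* Both lines keep the base service-time distribution by default
  (splitting beds does not change per-patient treatment time).  The
  alternative reading — line service *rates* summing to the base rate —
  is available as `literal_eq14`, implemented by slowing each line in
  proportion to its bed share.
* The admitted fraction x applies to both lines equally (acuity-specific
  admission probabilities are exposed as per-line overrides).

A practical sizing note: CTAS IV–V carry ≈ 41% of baseline arrivals, so an
express line on 20% of beds saturates once the ED runs hot
(the solver then reports `unstable:fast-track`); the directional benefits
(lower overall average wait, higher CTAS-III wait) reproduce when the
express share is near the demand share (≈ 0.4).

## Capacity planner

Targets are compared per class in hours after converting the
minute-denominated targets.  The minimum-capacity searches use a linear
scan (from ⌈λ/μ₁⌉ for the ED, from 1 for the IU) rather than bisection:
the pass verdict is not monotone in bed count under the wait chain (see
the known bias above), so a scan with a minimality certificate — returned
capacity passes, one bed fewer does not — is the only safe contract.  A
point passes only when the solver converges, the sufficient steady-state
condition holds on both queues, and every class meets its target.  Two
rigorous pre-checks (λ ≤ c₁μ₁ and xλ + λ_d ≤ c₂μ_I, both implied by the
sufficient condition) skip hopeless grid points cheaply.  The scan cap is
500 beds; reaching it reports infeasibility.

## Discrete-event simulator

An event-driven implementation of the physical system, used to validate
the analytic chain rather than to replace it.  Mechanics: per-class
Poisson arrival streams; preemptive-resume scheduling where an arriving
higher-acuity patient displaces the lowest-priority, latest-started
patient in service; on completion a patient needs an IU bed with
probability x; if the IU is full the patient boards, holding the ED bed,
and boarders claim freed IU beds FCFS ahead of simultaneous direct
arrivals (simultaneity is measure-zero with continuous laws; residual
ties fall back to event insertion order); direct arrivals finding a full
IU are lost.  Two deliberate divergences from the analytic abstraction,
both measurable with `compare_analytic_sim`: boarders are not preemptible
(their treatment is finished; the bed is physically occupied), and delays
are recorded to *first* treatment start while the analytic chain folds
interrupted waiting into the sojourn.

Statistics are collected per replication after a warmup and aggregated
across independent replications (seeded via `SeedSequence.spawn`; the same
seed reproduces results bit for bit) with t-based 95% confidence
intervals.  Default verification design: 200 replications × 2000 h
horizon × 200 h warmup — large replication counts only tighten the CIs,
so desk-scale runs use fewer.  The simulator is validated against exact
results: Erlang-C delays and sojourns for M/M/c (FCFS and class-1 /
aggregate identities under priorities), Erlang-B loss for M/M/c/c, and
Little's law as an internal consistency check on every stable run.

## Scenario fixtures

`make_fixture(seed, regime)` draws random valid scenarios with the
aggregate raw ED load targeted per regime (light < 0.3, moderate 0.3–0.7,
congested 0.7–0.95, unstable > 1) and the IU load drawn subcritically
(0.2–0.5 for light, 0.3–0.8 otherwise), splitting the IU flow budget
between transfers and direct admissions so the transfer share cannot
overshoot it.  The generator emulates steady-state mean flows only: no
within-day arrival profile, no day-of-week effects, no correlation between
acuity and treatment time, and a single pooled IU.  Tests passing on
these fixtures therefore demonstrate internal consistency of the solvers
across load regimes, not calibration to any particular hospital.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the dual-route fixed-point
comparison on 100 and 60 random scenarios respectively, simulate the
baseline with 200 × 2000 h (tests) and 100 × 1500 h (script)
replication designs, use 10⁶-draw Monte-Carlo oracles for the
order-statistic quadrature, and sweep the planning experiments on the
grids quoted in the README.  These sizes were chosen so the full suite
completes in a few minutes while keeping Monte-Carlo standard errors well
below the tolerances being asserted.

## Known limitations

* The wait chain's per-class estimates are upward-biased and
  non-monotone in c₁ (documented above); treat per-class numbers as
  conservative planning bounds and prefer aggregate system time for
  model-vs-data comparison.
* The blocking formula is reliable only at large c₂; small specialised
  units need the Erlang-B oracle or the simulator.
* Stationary analysis: no time-of-day staffing, no seasonal demand, no
  hall beds or bed-sharing, no cost model, and a single pooled IU.
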