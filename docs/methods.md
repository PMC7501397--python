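# Methods

## Model

The controller is a fixed-step stochastic-approximation scheme on the unit
interval. At trial t a task of difficulty d(t) is presented; the binary
outcome is modelled as x(t) ~ Bernoulli(S(d(t))), where the skill curve
S: [0,1] → [0,1] is monotone non-increasing. The update

    d(t+1) = min(1, d(t) + λ(1−s*))  on success,
    d(t+1) = max(0, d(t) − λs*)      on failure,

is identical to projecting the unconstrained move d + λ(x − s*) onto
H = [0,1]; the package implements the min/max form as the single code path
and keeps the projection form only as a property-test oracle
(`step_equivalence_check`). The expected one-step movement away from the
clips is exactly λ(S(d) − s*), so in rescaled time τ = λt the process
tracks the mean-field ODE ḋ = S(d) − s*, whose attractor is d* = S⁻¹(s*)
when min S ≤ s* ≤ max S (equality counts as interior), else the boundary 0
(max S < s*) or 1 (min S > s*).

## Parameters

* λ — step size, validated on the open interval (0, 1); exactly 0 or 1
  degenerates the update. Default in the simulation scenarios: 0.01.
  Governs the speed/precision trade-off: the e-folding time of the ODE
  linearised at d* is 1/(λ|S′(d*)|) trials, while the steady-state standard
  deviation around d* grows like √λ (OU approximation:
  √(λ s*(1−s*) / (2|S′(d*)|)) ≈ 0.016 at λ=0.01 for the standard learner).
* s\* — target success probability, open interval (0, 1); 0.7 in the main
  scenarios, 0.9 after the tracking switch.
* d(0) — initial difficulty, default 0.5 (a medium task); overridable.
* Skill curves: logistic S(d) = a − b/(1+exp(−k(d−center))) with
  0 < b ≤ a ≤ 1, k = 20, center = 0.5 by default (the family used in all
  published scenarios: a=b=1 interior case; a=0.6, b=0.5 lower-boundary;
  a=1, b=0.2 upper-boundary); a two-level step curve (the stochastic-
  point-location setting); and a piecewise-linear tabulated curve for
  property tests. No rounding of difficulty to a lattice is performed by
  the controller; the theory lives on the continuum.

## Estimators and numerical choices

* **Fixed-point inversion** is monotone bisection on [0,1], bracket
  tolerance 1e−10, cap 200 iterations. Flat segments resolve to the
  smallest difficulty attaining the target (easiest qualifying task); for
  a step curve and a target strictly between its levels this returns the
  jump location. The logistic closed form
  d = center − ln((b−a+s)/(a−s))/k is kept as an independent cross-check
  (agreement ≤ 1e−9 in tests).
* **ODE integration** is classical fixed-step RK4 with step 0.01 in
  rescaled time, state clipped to [0,1] after each step; validated against
  a 10×-finer reference (terminal agreement ≤ 1e−8). S is smooth and
  bounded, so adaptive stepping buys nothing here.
* **Stationary oracle.** For rational s\* = p/q the recursion started on
  the lattice {k·λ/q} stays on it (up-step q−p units, down-step p units,
  coprime), so the finite chain on that lattice — with sticky, not
  absorbing, boundaries, matching the min/max clips — *is* the continuum
  process, not a discretisation. Its stationary law is computed by power
  iteration on the half-lazy kernel (I+P)/2, which has the same stationary
  distribution but is aperiodic (the raw kernel is periodic: any closed
  interior walk uses a multiple of q steps), stopping at total-variation
  1e−12 between successive iterates. A nearest-grid-rounding mode exists
  for explicitly chosen grids and raises when the spacing does not resolve
  half the smaller step. Rounding grids are avoided by default because
  they distort the up/down step ratio (e.g. 7:3 → 5:2 at λ=0.001 on a
  6669-point grid), which visibly shifts the stationary mean.
* **Terminal-window statistics** use the last 10% of trials (minimum 100):
  comfortably past convergence in every scenario simulated here.
* **Replication** derives per-replicate seeds from a base seed by a fixed
  stride (10007), keeping all seeds below 2³¹; every trajectory records its
  seed and replays bit-exactly through the scalar update.
* **Scenario horizons**: 2000 trials for the three convergence cases and
  the λ ∈ {0.1, 0.01} sweep arms, 3000 for λ=0.001, 4000 with a switch at
  1500 for the tracking experiment — each visibly post-convergence for its
  step size. Monte-Carlo sizes (20–50 replicates) keep medians and window
  means stable at desk scale.

## Convergence-time measurement

Defining "converged" for a process whose steady state *oscillates* is
genuinely ambiguous, and the two natural definitions disagree:

* `convergence_time` — first trial from which |d − d\*| ≤ ε holds for the
  remainder of the run (ε = 0.05, at least 10 trials must follow). This is
  a last-exit statistic. Three caveats, all measured: (i) at λ = 0.1 the
  steady-state sd (≈0.056) exceeds the band, so runs essentially never
  settle by this rule; (ii) at λ ≤ 0.01 the start d(0) = 0.5 already lies
  inside the band around d\* = 0.458, so runs that never wander out report
  time 0; (iii) in between (λ = 0.01) the statistic is bimodal — about 40%
  of seeds report ~0 and half report the time of their last 3σ excursion,
  which also makes the value grow with the horizon. Its median should
  therefore not be read as "time to reach the optimum".
* `first_hitting_time` — first trial at which the trajectory reaches or
  crosses the limit. This is monotone in λ (medians ≈ 1 / 29 / 580 trials
  at λ = 0.1 / 0.01 / 0.001 for the interior case) and is what the
  speed/smoothness trade-off tests use; the smoothness side is measured as
  the terminal-window dispersion, which grows with λ.

The ODE timescale connects the two: contracting the initial offset takes a
fixed amount of rescaled time, i.e. O(1/λ) trials (about 4 e-foldings ≈
10/95/950 trials for the three λ values in the interior scenario, and ≈
350–500 trials to come within 0.05 of the boundary in the two boundary
scenarios at λ=0.01).

## What the simulated learners do and do not capture

The Bernoulli-with-static-curve learner isolates the controller: outcomes
are conditionally independent given difficulty, and the skill curve is
fixed for the whole session. Real learners improve with practice, fatigue,
and show sequential dependencies (streaks, warm-up); difficulty banks are
discrete, not continuous; and binary scoring discards partial credit. The
green test suite therefore demonstrates the controller's convergence and
tracking behaviour under its stated assumptions — not that a given human
will experience a 70% success rate; with a drifting skill curve the
controller tracks the moving fixed point with a lag of order 1/(λ|S′|)
trials, exactly as in the target-switch experiment. Mapping [0,1] to an
application's task bank (e.g. delay durations in titrated
matching-to-sample) is the caller's affine transform and is deliberately
out of scope.

## Known limitations

* Fixed λ only; decreasing (Robbins–Monro) schedules are out of scope.
* Binary outcomes only; graded feedback is out of scope.
* The stationary oracle's exact-lattice mode needs s\* rational with
  denominator ≤ 1000 and λ dividing the lattice into at most 200 001
  cells; other configurations fall back to rounding grids with their
  documented bias.
* The persistence-based convergence time is horizon-dependent by
  construction (see above); cross-study comparisons should prefer the
  first-hitting time or the ODE timescale.
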