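# bdtf — Balanced Difficulty Task Finder

Adaptive training works best when tasks are neither trivially easy nor
hopelessly hard. `bdtf` implements a stochastic-approximation controller
that tunes task difficulty, trial by trial, so that a learner ends up
succeeding at a chosen target rate s\* (say 70% — hard enough to challenge,
easy enough to stay motivating). It is aimed at people building adaptive
trainers, tutoring systems, psychophysics-style staircases or difficulty
balancing in games, and at anyone who wants to study such controllers in
simulation.

## The rule

Difficulty lives on `[0, 1]`. After each binary outcome `x(t)` the
difficulty of the next task is

```
d(t+1) = min(1, d(t) + λ(1 − s*))   if x(t) = 1   (success → slightly harder)
d(t+1) = max(0, d(t) − λ s*)        if x(t) = 0   (failure → easier)
```

with step size `λ ∈ (0,1)` and `d(0) = 0.5`. The update is *asymmetric*:
with s\* = 0.7 a failure moves difficulty down 7/3 times as far as a success
moves it up, so the expected movement vanishes exactly where the learner's
success probability equals s\*. If the learner's skill curve `S(d)`
(probability of success at difficulty d, monotone non-increasing) attains
s\*, the recursion converges to `d* = S⁻¹(s*)`; if even the easiest task is
failed too often (`max S < s*`) it settles at 0, and if even the hardest
task is too easy (`min S > s*`) at 1. In the small-λ limit the process
follows the mean-field ODE `ḋ = S(d) − s*`. λ trades speed for precision:
large λ converges fast but oscillates, small λ slowly but smoothly.

The package provides the controller (`bdtf.core`), simulated learners —
logistic, step, and tabulated skill curves (`bdtf.learners`) — the ODE /
expected-drift / stationary-distribution analysis layer (`bdtf.analysis`),
a session and replication engine including mid-session target changes
(`bdtf.simulation`), and config/CSV I/O plus a CLI (`bdtf.io`, `bdtf.cli`).
It can also drive a *real* session: feed it a log of recorded outcomes and
it returns the next difficulty to present (`next_difficulty`, `bdtf next`).

## Worked example

The standard simulated learner is `S(d) = a − b/(1 + exp(−20(d − 0.5)))`.
With a = b = 1 and target s\* = 0.7:

```
$ bdtf fixed-point --target 0.7
case=interior d_star=0.457635
```

so the controller should settle near d\* ≈ 0.458, where the learner succeeds
70% of the time. An independent check — the stationary distribution of the
exact finite-state chain the update induces on its step lattice:

```
$ bdtf oracle --lam 0.01 --target 0.7
stationary_mean=0.456630 grid_n=1001
```

(the small gap below 0.458 is the real O(λ) stationary bias, which shrinks
to 0.4575 at λ = 0.001). A learner whose best success rate is only 0.6 can
never meet a 0.7 target, and the controller correctly backs off to the
easiest tasks:

```
$ bdtf fixed-point --a 0.6 --b 0.5 --target 0.7
case=lower_boundary d_star=0.000000
```

Mid-session retargeting — a teacher deciding after 1500 trials that the
learner should succeed 90% of the time instead of 70% — moves the operating
point from S⁻¹(0.7) ≈ 0.458 to S⁻¹(0.9) ≈ 0.390:

```
$ bdtf track --lam 0.01 --steps 4000 --switch-t 1500 --seed 1
pre_switch_mean=0.4584 post_switch_mean=0.3867
```

(window means of a single stochastic run; they fluctuate by a few
hundredths around the fixed points). Online use from a recorded log:

```
$ cat log.csv
t,d_presented,x
0,0.5,1
1,0.503,0
$ bdtf next --log log.csv --lam 0.01 --target 0.7
next_difficulty=0.496000
```

`bdtf reproduce fig2|fig3|fig4|fig5|fig6 --out-dir out/` re-runs the
published simulation scenarios (three convergence cases, the λ sweep, the
target change) and writes trajectory CSVs and a JSON convergence report;
`bdtf simulate --config run.yaml` runs replicated sessions from a YAML
config (see `bdtf.io` for the schema).

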