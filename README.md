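# bondperm

Dyadic allogrooming rates and constrained-permutation inference for
forced-proximity experiments on captive social animals.

## The problem

Animals that spend time close together often also cooperate more — but does
proximity *cause* cooperation, or do cooperative partners simply seek each
other out?  A clean way to answer this is an experiment: let a colony of
mutually unfamiliar individuals (here, female common vampire bats from three
distant capture sites) associate freely, then force randomly chosen
cross-site triads into small cages for a short period, release everyone, and
ask whether the caged pairs keep grooming each other more than comparable
pairs that were never caged.

`bondperm` implements the full analysis for this design, for behavioural
ecologists and anyone analysing dyadic interaction rates under a constrained
randomisation:

* **Rates.** For each unordered pair and phase (PRE / FORCED / POST), the
  *allogrooming log rate* is `ln(1 + x)` with
  `x = (r_a→b + r_b→a) / 2`, where each directed rate is total grooming
  seconds divided by the pair's shared exposure hours.  Pairs are classified
  as **test** (different sites, caged together), **control** (different
  sites, never caged) or **familiar** (same site).
* **Group comparison.** Per-class mean changes `Δ = rate_log(POST) −
  rate_log(PRE)` with percentile-bootstrap 95% CIs.
* **Constrained permutation test.** The null re-randomises the treatment
  assignment itself: bats are re-drawn into possible new site-complete
  triads (the 3×7 design admits `(7!)² = 25,401,600`), dyad labels follow
  the new cages, and the TEST−CONTROL mean change is recomputed with the
  observed per-dyad rates held fixed.  One-sided
  `p = (1 + #{null ≥ observed}) / (1 + n_perm)`, with automatic exhaustive
  enumeration when the assignment space is small.
* **Follow-ups.** The per-bat shift in the proportion of grooming aimed at
  unfamiliar partners; the familiar-vs-unfamiliar trade-off correlation;
  rank linear models of test-dyad grooming with one-sided permutation
  p-values from shuffling forced-phase rates within each cage; Spearman
  correlations between phase rates; robustness filters (high-baseline
  controls, under-sampled or infected bats); windowed rates for time-course
  reporting.
* **Synthetic colonies.** A generator with the design baked in (Poisson
  bout streams, log-normal dyad heterogeneity, shifted-exponential bout
  durations ≥ 5 s, a tunable treatment effect on the analysis scale), so
  every stage is testable without any external data.

## Worked example

```python
from bondperm import (SimConfig, generate_colony, dyad_changes,
                      group_change_summary, triad_permutation_test)

colony = generate_colony(SimConfig(seed=1))       # 21 bats, 0.5 injected effect
changes = dyad_changes(colony)
summary = group_change_summary(changes, n_boot=5000, seed=10)
perm = triad_permutation_test(colony, n_perm=5000, seed=11)
```

Running `python examples/03_group_changes_permutation.py` (which does the
above) prints:

```
test_mean_change       +0.514  95% CI [+0.435, +0.596]
control_mean_change    -0.007  95% CI [-0.046, +0.035]
familiar_mean_change   -0.021  95% CI [-0.064, +0.024]

test - control difference = +0.521 log s/h
one-sided permutation p = 0.0002  (5000 re-assignments)
```

The test dyads' grooming rose by about 0.51 log s/h while control and
familiar dyads stayed flat — recovering the 0.5 log-scale effect this
synthetic colony was generated with — and essentially no alternative triad
assignment places that much increase on exactly the caged dyads, hence the
small permutation p.  The other `examples/` scripts walk through the
generator, the rate tables, and the rank-model follow-ups.

A thin CLI mirrors the stages: `bondperm simulate`, `bondperm rates`,
`bondperm infer`, and `bondperm run --config run.yaml` for a one-shot
reproducible run (outputs include `rates.csv`, `results.csv`, a windowed
time-course table, a markdown summary and a manifest with seeds and a
config hash).

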