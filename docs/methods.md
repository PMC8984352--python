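# Methods

## Design and quantities

The package analyses a three-phase forced-proximity experiment on a captive
colony: a free-association baseline (PRE, default 42 days), a short period
in which the colony is partitioned into small cages (FORCED, 7 days) — each
cage a *triad* holding exactly one bat from each capture site, so cage-mates
are previously unfamiliar — and a second free-association period (POST, 63
days).  Daily video sessions of 3–6 h record directed allogrooming bouts of
at least 5 s (actor, receiver, duration).

**Exposure.** A pair's exposure in a phase is the total sampled hours
during which both members could physically interact: all session hours in
PRE and POST, and only cage-mates' hours during FORCED.  Cross-cage pairs
have zero FORCED exposure and their FORCED rate is *missing*, never zero.

**Allogrooming log rate.** For a pair with exposure `H > 0` in a phase,

```
rate_log = ln(1 + x),   x = (S_a→b / H + S_b→a / H) / 2 = S_pair / (2H)
```

where `S` are total grooming seconds.  The two directions are averaged
because allogrooming is largely bidirectional; the `ln(1 + ·)` transform
stabilises a variance that grows with the mean.  "Seconds per hour averaged
across hours" is implemented as total seconds over total hours — the
exposure-weighted mean — which agrees with a per-hour average under equal
sampling and stays well defined for fractional hours.

**Dyad classes.** FAMILIAR = same capture site; TEST = different sites and
same triad; CONTROL = different sites, different triads.  The classes
partition all C(n,2) pairs; for the default design (3 sites × 7) that is
21 TEST + 126 CONTROL + 63 FAMILIAR = 210.  The effect of interest is the
TEST−CONTROL difference in mean change `Δ = rate_log(POST) − rate_log(PRE)`.

## Inference

**Percentile bootstrap.** CIs for mean changes resample the unit each mean
averages over — dyads for class means, bats for per-bat statistics — with
replacement, taking empirical α/2 and 1−α/2 quantiles of the resampled
means (default 5000 resamples, 95% level).  Dyads sharing an individual are
not independent; the bootstrap ignores this, which is a recognised
limitation of dyadic data and is partly why the primary p-value comes from
the design-based permutation test instead.

**Constrained permutation test.** Because the treatment was a random
site-complete partition into triads, the exact null distribution of any
statistic is obtained by re-randomising that partition.  With `s` sites of
`n` bats there are `(n!)^(s−1)` distinct partitions (anchoring one site
removes the triad-labelling symmetry).  For each re-assignment, TEST/CONTROL
labels are recomputed and the TEST−CONTROL mean of the *fixed* observed
per-dyad changes is taken; familiar dyads never enter.  The one-sided upper
p-value uses the add-one correction `(1 + #{null ≥ obs}) / (1 + n_perm)`,
so `p ≥ 1/(n_perm+1)`; when the partition space has at most
`exhaustive_cap` members (default 100,000) it is enumerated instead and the
p-value is the exact tail proportion.  One-sidedness matches the directional
hypothesis (forced proximity should *increase* grooming); `alternative=`
switches it.

**Per-bat statistics.** The proportion of a bat's total allogrooming log
rate directed at different-site partners is computed per phase; the
statistic is the mean POST−PRE shift over bats (summing log rates follows
the headline definition; a `use_raw` flag sums back-transformed s/h rates
instead).  A bat with zero total rate in a phase has an undefined proportion
and is dropped with a warning.  The trade-off statistic is the Pearson
correlation, over bats, between the mean change toward familiar partners
and toward unfamiliar partners, with a bat-resampling bootstrap CI and the
standard two-sided Pearson test as p-value.

**Rank models.** Within the test dyads: OLS of rank(Δ) on rank(FORCED
rate), and OLS of rank(POST) on rank(PRE) + rank(FORCED), midranks for
ties.  The reported permutation p shuffles the raw forced-phase rates
*within each cage* (independent shuffles of each triad's three dyads),
re-ranks, and refits — preserving cage structure under the null that
within-cage grooming order is uninformative.  With 7 cages the arrangement
space is 6⁷ = 279,936, above the default exhaustive cap, so Monte-Carlo
sampling is used at full scale and exhaustive enumeration on small designs.
A two-sided parametric OLS t-test accompanies each permutation p as a
descriptive companion.  Permutation refits use the closed-form normal
equations; the observed fit is done with statsmodels and the two agree to
numerical precision.

**Robustness filters.** (i) `high_pre_controls` excludes control dyads
whose PRE rate exceeds the maximum PRE rate among test dyads (guarding the
group comparison against regression to the mean); the exclusions ride on
the colony as `excluded_dyads` and are honoured by the change table and
every statistic built on it.  (ii)/(iii) flag-based filters drop
under-sampled or infected bats with all their dyads; triads may then be
incomplete, which downstream classification handles.

## Synthetic colony generator

For each unordered pair, both grooming directions are Poisson with per-hour
intensity

```
lambda = base_rate_lambda * familiarity_multiplier^[same site] * exp(eps),
eps ~ Normal(0, dyad_sd)   (shared by both directions)
```

and bout durations are `5 + Exponential(bout_mean_s)` seconds, so every
bout clears the 5 s scoring floor and a pair's expected grooming is
`x = lambda * D` s/h with `D = 5 + bout_mean_s`.  This is the simplest
process giving overdispersed, heterogeneous dyadic rates with a hard
minimum duration.

**Treatment effect.** `treatment_effect_delta` is defined on the scale the
analysis measures: for cage-mates in treated phases (FORCED and POST by
default; POST only with `treatment_in_forced=False`) the intensity is
inflated to `lambda' = ((1 + x) e^delta − 1) / D`, which shifts the
expected allogrooming log rate `ln(1 + x)` by exactly `delta`.  This makes
the TEST−CONTROL difference estimator unbiased for `delta` by construction
and `delta = 0` an exact null.  A pair with `lambda = 0` stays silent — a
nonexistent behaviour cannot be boosted.

**Defaults** (chosen once to give realistic spreads; pre-phase log rates
mostly 0.3–2 log s/h):

| parameter | default | meaning |
|---|---|---|
| `n_sites`, `bats_per_site` | 3, 7 | 21 bats, site-complete triads of 3 |
| `phase_lengths_days` | (42, 7, 63) | 6/1/9 weeks |
| `hours_per_day` | (3, 6) | uniform draw per day, hours |
| `base_rate_lambda` | 0.04 | directed bouts per hour, unfamiliar pair |
| `familiarity_multiplier` | 3.0 | same-site rate multiplier |
| `dyad_sd` | 0.8 | sd of the log-normal dyad effect |
| `bout_mean_s` | 25 | mean bout duration above the 5 s floor |
| `treatment_effect_delta` | 0.5 | log-rate shift for treated dyads |

Reproducibility: one master seed; sessions, triads and every pair own
substreams keyed by stable identities (site and within-site indices), so
enlarging a colony does not reshuffle existing pairs' draws.
`generate_null_ensemble` derives per-dataset seeds deterministically and
forces `delta = 0`.

**What the generator does not emulate:** diurnal or seasonal rhythms,
directed-rate asymmetry (the dyad effect is symmetric), social contagion or
network reciprocity beyond the pair, food sharing, and demographic
structure.  Passing tests therefore show the *inference machinery* is
correct and calibrated for rate-structured data of this shape — not that
real colonies satisfy the Poisson/log-normal assumptions.

## Numerical and design choices

* Canonical dyad key: lexicographic on `bat_id`; all tables use it.
* Zero exposure ⇒ missing rate (NaN), propagated, never coerced to 0;
  change scores require positive exposure in both PRE and POST.
* Ties: midranks throughout; all-tied vectors raise a
  `DegenerateStatisticError` rather than returning NaN.
* Degenerate bootstrap resamples of a correlation (constant vector) are
  dropped via NaN-aware quantiles.
* CSV interchange: comma-separated UTF-8, header row, ISO-8601 dates;
  floats round-trip exactly (`float_precision="round_trip"` on read).
  Phase calendar bounds are inferred from the sessions table.
* Validation is strict by default; a lenient mode drops (with a warning)
  FORCED-phase bouts between different cages instead of failing.
* Test problem sizes: the calibration suite uses 200 null colonies at the
  full 21-bat design with 500 permutations each, and parameter recovery
  uses 200 replicates — sizes at which binomial/Monte-Carlo error bounds
  in the tests are meaningful while the whole suite stays quick.

## Known limitations

* Dyadic non-independence is addressed by the design-based permutation
  test for the headline comparison, but bootstrap CIs treat dyads/bats as
  exchangeable units.
* The FORCED-phase rate exists only for test dyads; analyses that need all
  three phases are therefore restricted to test dyads by construction.
* The proportion-shift statistic sums log-transformed rates, which is a
  definition, not a measurement of time budget; the raw-rate variant is
  provided for sensitivity analysis.
* Mixed-effects modelling of the changes is intentionally out of scope;
  the permutation and bootstrap machinery is the contribution here.
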