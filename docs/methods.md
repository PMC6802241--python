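# Methods

## The model

`edsim` is an individual-level (microsimulation) Markov state-transition
model of eating-disorder (ED) life courses. Each simulated person occupies
one of six states per year of age — healthy, anorexia nervosa (AN), bulimia
nervosa (BN), binge-eating disorder (BED), other specified feeding and eating
disorders (OSFED), or deceased — and is followed from birth through age 40 in
annual cycles. Cohorts are 50% male / 50% female by construction; all disease
parameters are sex-specific. The deceased state is absorbing; every other
transition is allowed.

Within one cycle, events resolve in a fixed order:

1. **Death**, from the start-of-year state. Healthy persons die with the
   background life-table probability `q(sex, age)`; persons in an ED state
   die with the SMR-scaled probability `1 - (1 - q)^SMR` (multiplication on
   the rate scale keeps the result a probability).
2. **One multinomial for survivors.**
   - *Healthy, never affected*: first-ever ("naive") onset of each ED with
     age- and sex-specific probability `p_naive(ed, sex, age)`; the four
     curves are mutually exclusive alternatives.
   - *Healthy, previously affected*: relapse into the most recent ED with a
     declining-exponential hazard
     `p(y) = p_first * exp(-decay * (y - 1))`, where `y >= 1` counts years
     since the last remission (so the first post-remission year has
     probability `p_first` exactly). Persons with any ED history never
     re-enter the naive-incidence process; all re-onsets flow through
     relapse. The geometric alternative `p_first * decay^(y-1)` was
     considered and not used.
   - *In an ED state*: remission to healthy, direct crossover to one of the
     other three EDs, or persistence. Remission uses the untreated
     probability `p_base`, or `1 - (1 - p_base)^RR` in a treated year
     (a rate-ratio effect; treatment affects nothing else). Treatment is an
     independent annual Bernoulli(coverage) draw per prevalent person-year.

The relapse clock resets on every remission to healthy; crossover does not
reset it and does not end an "overall" episode. An overall episode is a
maximal contiguous run of years in *any* ED state; a per-ED episode is a
maximal contiguous run in that specific state.

### Randomness and common random numbers (CRN)

All stochastic decisions consume a pre-drawn uniform array indexed by
(person, age, decision channel) — channels for death, onset/relapse, ED-type
pick, treatment assignment, and the remission/crossover outcome. Because
draws are indexed positionally rather than consumed from a sequential
stream, two scenarios simulated from the same master seed give every person
identical randomness, and counterfactual contrasts (deaths averted) are
paired at the person level. The same mechanism fixes the evaluation
randomness within one calibration search, making the annealer's loss surface
deterministic in the parameters.

Scenarios toggle two switches: treatment mode (`current` coverage, `none`,
`full`) and incidence on/off. The four analysis scenarios are the
current-treatment baseline, no treatment, full treatment, and zero incidence
(prevention).

## Parameters and priors

All scalar parameters live in a `ParameterSet` (relapse `p_first` and
`decay`, untreated remission, treatment coverage and efficacy, 12 ordered
ED-crossover probabilities per sex, four SMRs per sex), plus the incidence
curves and the life table. The shipped fixture
`src/edsim/data/table1.csv` carries the published uniform prior search
bounds and the published calibrated means/UIs for all 72 scalars, on their
printed scales. A handful of printed calibrated means lie above their own
printed prior bounds (e.g. BED male remission 16.3% vs a 0–10% bound); the
fixture stores both as printed, the sampler respects the bounds, and
pipelines that fix parameters "at calibrated means" use the printed means
unchanged.

Naive incidence is parameterised as a fixed age *shape* (peak normalised
to 1) times one calibrated scalar multiplier per (ED, sex) — 8 free
scalars. `calibrate_multiplier_to_cumulative` anchors a multiplier to a
published cumulative-incidence figure over an age window by root-finding on
`1 - prod(1 - m * shape[a]) = target`, capped so the full curve stays a
valid probability.

**Validity and repair.** A parameter set is valid when, for every
(ED, sex, age), death + treated remission + outgoing crossovers ≤ 1, and for
every (sex, age), total naive incidence + background death ≤ 1. When a prior
draw is invalid, the lower bounds of the parameters in the violated sum are
iteratively lowered (×0.9 per iteration — the multiplicative step preserves
nonnegativity; the published procedure specifies "iteratively lowered"
without a rate) and the draw repeated; more than 100 repairs raises an
error.

## Calibration

Goodness of fit is the quadratic loss `sum_i w_i (target_i - sim_i)^2` with
`w = 1/SE` (inverse-SE weighting as published; classical inverse-variance
`1/SE^2` is available as a config option). Each simulated-annealing search:

- starts from a uniform prior draw (with bound-lowering repair);
- evaluates candidates on one fixed-seed simulated cohort (CRN across
  iterations; `sim_size` configurable);
- proposes uniform jitter of `proposal_scale` (default 0.1) × bound width on
  a random ~25% subset of parameters, clipped to bounds and repaired if
  invalid;
- accepts by the Metropolis rule with geometric cooling
  `T_k = T0 * alpha^k`; `T0` defaults to the initial score and `alpha` to
  the value reaching `1e-3 * T0` at the final iteration (the proposal
  distribution, cooling schedule and T0 are not published; these defaults
  are exposed in `AnnealConfig`);
- returns the best-ever visited set.

The best `keep_k` end-of-search sets (ties broken by search seed) form the
calibrated ensemble; per-parameter means and empirical 2.5/97.5 percentiles
give the calibrated-values summary. Two profiles ship: the full-scale
profile (10,000 searches × 1,000 iterations, 100,000-person evaluations,
keep 100) mirroring the published analysis, and the desk profile
(200 × 500 at 20,000 persons, keep 100) used by the packaged reproduction
and sized to run on one CPU in minutes.

**Default targets.** The original survey target set is not published. The
shipped default anchors are the published headline estimates — peak annual
any-ED prevalence at age 21 (male 7.4%, female 10.3%) and cumulative
lifetime any-ED prevalence at age 40 (14.3%, 19.7%) — with SEs recovered
from the published 95% UI widths (width/3.92). Users with real survey
targets should supply them as CSV (`kind, ed, sex, age_lo, age_hi, value,
se`); the calibration machinery is identical. Four any-ED anchors cannot
identify the per-ED mix of eight multipliers; the mix is therefore governed
by the relative prior bounds (below), and ensemble spread propagates the
remaining indeterminacy into all downstream uncertainty intervals.

## Outcome definitions

- **Annual (12-month) prevalence** at age *a*: persons occupying a matching
  ED state during year *a* over persons alive during year *a*.
- **Lifetime prevalence** at age *a*: cumulative incidence — first matching
  onset at or before *a* over the full birth cohort. Deaths stay in the
  denominator so the curve is nondecreasing; a survivor-conditioned variant
  (what a cross-sectional survey would measure) is available and is the
  natural choice when matching survey-based targets. The two differ by well
  under one percentage point before age 40 at realistic mortality.
- **Naive-incidence CDF**: distribution of age at first-ever onset among
  ever-affected persons; reaches 1 at age 40 by construction.
- **Episode distribution**: overall episode counts binned 1, 2, 3, 4, 5+,
  conditional on at least one episode.
- **Deaths averted**: difference in cumulative deaths by 40 between two
  CRN-paired scenario runs, per 100,000 persons.
- **Uncertainty**: statistics are computed per run; ensembles report the
  mean, median and the 2.5th/97.5th empirical percentiles (95% UI). Runs
  redraw both the random streams (first-order uncertainty) and the
  parameter set, sampled uniformly with replacement from the calibrated
  ensemble (second-order uncertainty).

## Synthetic inputs

Three inputs are external data in the original analysis and are generated
synthetically here (any CSV replacement can be dropped in):

- **Life table** — Gompertz–Makeham hazard
  `q(a) = 4e-4 + 2.5e-5 * exp(0.105 a)`, male multiplier 1.7, chosen to
  approximate US pre-40 mortality levels (female q rises from ~4e-4 at
  birth to ~1.9e-3 at 39; ~2.7%/4.5% of females/males die before 40). It is
  smooth and parametric: no infant-mortality hump, no period effects.
- **Incidence shapes** — log-normal densities of age with peaks AN 15,
  OSFED 16, BN 17, BED 19 and log-SDs 0.20/0.20/0.22/0.25: unimodal,
  adolescent-peaked, right-skewed curves consistent with the reported
  concentration of first onsets before age 25 (BED later and more
  dispersed). Both sexes share the shape; sex differences live in the
  multipliers.
- **Multiplier prior bounds** — anchored to household-survey lifetime
  prevalence for the specific disorders (AN 0.3% male / 0.9% female, BN
  0.5%/1.5%, BED 2.0%/3.5%; upper bound ≈ 2 × lifetime/9 per onset-window
  year), with a wide bound for OSFED as the residual category carrying the
  bulk of cases. These bounds matter: they set the ED mix the any-ED
  anchors cannot identify, and through the mix the SMR- and
  treatment-weighted mortality contrasts.
- **Targets** — survey-style targets are generated by simulating a large
  cohort under a known truth and adding binomial noise at survey sizes,
  `se = sqrt(p(1-p)/n)`; survey design effects (clustering, weighting) are
  not emulated.

What passing recovery tests on these inputs shows: the calibration machinery
can recover the prevalence curves (the identifiable quantity — raw
parameters are not identifiable) that generated its targets, within the
targets' sampling noise. What it does not show: that the synthetic shapes,
life table or bounds equal the unpublished originals, or anything about
secular trends, covariate-dependent risks, ARFID, or open-population
dynamics, all of which are out of scope.

## Numerical notes

- The person-year loop is numba-compiled; one 20,000-person cohort
  simulates in a few milliseconds, which is what makes ~10^5 calibration
  evaluations practical on one CPU.
- Uniforms are drawn as float32 (PCG64); all probability arithmetic is
  float64. Outcome distributions sum to 1 to 1e-12 by construction.
- `calibrate_multiplier_to_cumulative` solves to 1e-10 with Brent's method.
- Percentiles use linear interpolation (numpy default) everywhere.
- Ensemble selection breaks score ties by search seed, so results are
  reproducible regardless of search scheduling.
- Degenerate inputs: zero-incidence parameter sets, all-zero shapes and
  empty target subgroups raise informative errors rather than NaNs; the
  survivor-conditioned lifetime tally is maintained for any-ED targets only
  (per-ED survivor conditioning falls back to the per-person route).

## Reproduction pipeline and problem sizes

`edsim.reproduction.reproduce(seed)` — also driven by
`scripts/acceptance.py` — fixes all 72 published scalars at their printed
calibrated means, calibrates the 8 incidence multipliers to the printed
anchors at the desk profile (200 × 500 × 20,000), then summarizes a 100-run
× 20,000-person ensemble of the four scenarios. These sizes are the
package's desk-scale defaults, a deliberate 1:5 reduction of the published
cohort (100,000) and 1:10 of its run count; headline means are stable to
well within the published UI widths at this scale, while per-run scatter
(hence UI width) is somewhat larger than at full scale. The full-scale
profile is available via `AnnealConfig.paper()` and
`simulate_ensemble(n_runs=1000, n_persons=100_000, ...)`.

## Known limitations

- The published survey targets, GBD-derived incidence curves and US life
  table are not in the public text; all three are replaced by documented
  stand-ins, so parameter-level agreement with the published calibrated
  values is not expected (and the published "87% of targets within CI" fit
  statistic is not reproducible).
- The ED mix is prior-driven (see above); quantities weighted by the mix
  (deaths averted under treatment scenarios) inherit that prior.
- Treatment status is redrawn annually; whether treatment persists across
  years of a continuing episode is not published. Naive incidence of a
  *different* ED after full remission of a first type is disallowed
  (relapse-only re-onset); the published text is ambiguous on this point.
- One annual cycle means within-year episodes shorter than a year are
  invisible; episode counts are therefore counts of distinct affected
  years-runs.
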