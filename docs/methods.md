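# Methods

`agesocnet` studies how age-based changes in individual social
behaviour scale up to the structure of animal social networks, using
the adult-female grooming system of rhesus macaques as its template.
It has four scientific components: a generative network model, a metric
suite, a synthetic longitudinal data generator, and hierarchical
regression models. This note records the models, their assumptions, the
defaults and why, and the numerical conventions.

## The kin-structured, age-stratified network model (`abm`)

A group of *n* = 50 females is partitioned into 10 kin groups
(matriline blocks) of 5. Each female is *old* or *young*; the number of
old individuals `n_old` is drawn per network from the discrete uniform
distribution on {0, …, 50} (counts of individuals are integers, so the
continuous phrasing of a uniform range is interpreted discretely). Age
labels and kin labels are assigned by independent uniform permutations.
Every dyad then belongs to one of six types (age-class pair × kinship)
and receives an edge by an independent Bernoulli draw with the
dyad-type linking probability:

| dyad type | probability |
|---|---|
| old/old kin | 0.33 |
| old/old non-kin | 0.02 |
| old/young kin | 0.37 |
| old/young non-kin | 0.05 |
| young/young kin | 0.27 |
| young/young non-kin | 0.08 |

These defaults are the mean proportions of linked dyads of each type
observed across 19 empirical macaque grooming networks. The model has
no dynamics: each network is a single static draw (no rewiring, births,
deaths, continuous ages, sexes, or space).

**Analytic oracle.** Because age labels are assigned by sampling
without replacement, the probability that a given dyad is old/old is
`n_old (n_old−1) / (n(n−1))` (and similarly for the other age pairs),
while kin/non-kin dyad counts are fixed by design (100 kin, 1125
non-kin dyads). `expected_mean_degree` sums expected dyad counts times
their probabilities; at the extremes it gives 4.68 (all young) and 2.22
(all old). Monte-Carlo runs are held to this closed form within
sampling error.

**Experiments.** The verification run (10 000 networks) compares
realized linking proportions per dyad type to the input table; per
replicate the proportion is computed only over dyads of that type
(types absent from a replicate contribute nothing). The full-range run
(default 20 000 networks, a size at which the binned curves are smooth;
configurable upward) summarises mean degree, diameter and transitivity
in 20 equal-width proportion-old bins. The restricted-range experiment
mirrors the empirical design: proportion old limited to [0.04, 0.20]
(integer `n_old` from ceil(0.04·n) to floor(0.20·n), i.e. {2,…,10}),
19 networks per bout, 50 bouts, with an OLS trend of each metric on
proportion old per bout. Trend fitting uses plain least squares — the
simplest estimator matching a linear smoother. The sensitivity sweep
perturbs the probability table multiplicatively (±10%, ±20%, jointly
and per entry; values clamped to [0,1] with a logged warning) and
reports the sign of linear and quadratic trends of each global metric,
since the exact perturbation scheme used in the original sensitivity
analysis is not recoverable; the closed-form mean-degree curve is also
checked directly under perturbed tables.

## Network metrics (`metrics`)

Node metrics: weighted eigenvector centrality, shortest-path
betweenness, closeness, binary local clustering, plus degree and
strength. Global metrics: mean (binary) degree, diameter, transitivity
(3 × triangles / connected triples, binary), density.

Conventions, chosen where the field's definitions fork on weighted or
disconnected graphs:

* **Weight → distance.** Edge weights are grooming rates (affinities);
  geodesic computations use reciprocal weights rescaled per network so
  the strongest edge has unit length. Shortest paths, and hence
  betweenness and the diameter's argmax pair, are invariant to the
  common rescaling; its purpose is to bound closeness: every edge is at
  least one distance unit, so closeness cannot exceed 1. On unit-weight
  (binary) graphs all of this reduces exactly to hop counts.
* **Closeness** uses the bounded reachable-set formula
  `((r−1)/(n−1)) · ((r−1)/Σ d)` with `r` the size of the node's
  reachable set; isolates score 0. This keeps the score in [0,1] (as a
  Beta-family response model requires) and defined on disconnected
  graphs.
* **Diameter** is the longest geodesic over connected pairs only, so it
  stays finite on the sparse old-heavy networks; an edgeless graph gets
  0 with a flag.
* **Eigenvector centrality** is computed per connected component by
  dense symmetric eigendecomposition (component vectors L2-normalised,
  nonnegative) and the whole vector is rescaled to maximum 1; isolates
  score 0 and are excluded (with a logged count) from log-scale
  response models downstream.
* **Clustering** is binary even on weighted graphs, which yields exact
  0s and 1s consistent with endpoint-inflated unit-interval response
  models; degree-<2 nodes get 0.
* **Betweenness** is reported raw and possibly fractional; rounding for
  count-family models happens in the modelling layer, keeping
  measurement and modelling separate.

Implementation leans on networkx (node metrics) and igraph (global
metrics, where ensemble throughput matters); the test suite holds every
metric to independent brute-force oracles (Floyd–Warshall with explicit
path counting, power iteration, triangle enumeration) and to a second
graph library.

## Synthetic grooming data (`synth`)

The generator emulates the *structure* of the empirical data so the
full pipeline can be exercised and validated without it: 6 groups
followed over an 8-year window contributing 19 group-year networks in
the unbalanced pattern 8/2/3/2/1/3; ~50 adult females per group-year;
adulthood from age 6; matrilines of mean size ≈ 5; ranks assigned from
a latent order with the 80% / 50% dominated cutoffs for
high/medium/low.

**Demography.** Adult lifetimes are geometric with hazard
`1 − 0.5^(1/12)` per year, giving a median death age of 18, truncated
at 30. A fixed-size group with that mortality alone would equilibrate
near 30% old (>18 y), far above the observed 3–19%; the initial age
pyramid is therefore young-skewed (`P(age) ∝ 0.80^(age−6)`), emulating
a growing population, and deaths are replaced by newly adult recruits
joining existing matrilines. Over the window the proportion old drifts
upward through the observed range. Females average ≈ 2.8 observed
years (range 1–8), an emergent consequence of survival and the
observation design.

**Ties and weights.** A dyad's tie probability is logistic:
each endpoint contributes her rank effect, an individual intercept, and
`partner_slope` × (age − 10); same-matriline dyads add a kin bonus that
grows with the dyad's mean age (`kin_bias_slope`). Defaults
(`base −2.3`, `kin bonus 1.45`, `partner_slope −0.06`/yr,
`kin_bias_slope 0.19`/yr of mean age) were calibrated from the six
empirical linking proportions above — the logit differences across
young/old endpoint swaps give roughly −0.06 per own-age year for
non-kin ties and a kin bonus growing fast enough that kin ties hold
steady while non-kin ties are lost. This reproduces the system's
documented pattern: partner numbers fall within-individual, the kin
share of partners rises, and (because each female's total grooming time
is drawn age-invariantly from a Gamma and split over her partners by a
symmetric Dirichlet) remaining ties strengthen. Rates are dyadic
seconds divided by the dyad's combined observation hours (2 × 60 h).
The average-relatedness covariate per network is a kinship proxy: 0.25
times the share of within-matriline dyads.

**What it does not emulate.** Real degree and weight distributions are
not reproduced (only the printed summary facts are targeted); there is
no male/juvenile structure, seasonality, observation error in edge
weights, or pedigree relatedness. Passing pipeline tests on this
generator validates the estimators under a known truth, not the
empirical effect sizes.

Every dataset carries a `TruthRecord` (generating slopes, rank
interaction, per-individual random slopes, per-network proportion old).

## Trajectory and global-structure models (`trajectory`)

Age is decomposed per female into `average_age` (between-individual)
and `delta_age` (within-individual); the decomposition is an exact
linear bijection, tested to machine precision.

Metric trajectories are modelled on rows aged 10+ with fixed effects
`delta_age`, `average_age`, rank, optionally rank × `delta_age`; the
interaction is dropped and the model refitted when no interaction term
has a 95% interval excluding zero. Random structure: intercepts for
individual, group, year, **and group-year (network)**, plus a
`delta_age` random slope per individual, all as crossed variance
components in a REML linear mixed model. The network component is
essential: all members of a group-year share one network realization,
and because panel members age in lockstep those shared shocks otherwise
alias into the within-individual age contrast — null-data calibration
fails without it.

Response families map each metric to an approximately Gaussian working
scale: log for eigenvector (isolates excluded with a logged count),
log1p of rounded values for betweenness (counts; no explicit
zero-inflation component — no available likelihood engine fits mixed
zero-inflated families, and parameter recovery is the contract), and an
empirical-logit squeeze for closeness and clustering (boundary values
pulled inside (0,1) by `(y(n−1)+0.5)/n`). Continuous predictors are
standardized internally; coefficients are reported on that scale with
the transform recorded. Intervals are Wald 95%. A two-stage fallback
(per-individual OLS slopes, precision-weighted pooling) is kept as a
sign cross-check.

**Validation.** The estimator is validated by parameter recovery, not
by matching any particular sampler. The recovery configuration uses a
clearly non-null generating decline (`partner_slope = −0.18`, no kin
compensation) with degree — the direct observable of the generating
effect — as the response: the test demands sign recovery with interval
exclusion in ≥ 90% of replicates, and ≤ 15% false exclusions on null
data (all slopes zero). At the data-calibrated defaults the 19-network
design has only partial power for the indirect metrics — the same
marginal detectability the empirical analysis reports, and the central
point of the restricted-range experiment.

Global-structure models regress mean degree, log diameter, or
transitivity on proportion old, with average relatedness as a covariate
when present, density added for diameter and transitivity, and a year
random intercept when years vary (falling back to OLS when the mixed
fit degenerates, recorded in the result). Constant responses return a
degenerate fit with a warning rather than an error.

## Numerical and design notes

* All randomness flows through `numpy.random.Generator`; every
  experiment takes a master seed and is bit-reproducible from its
  manifest (experiment name, config hash, seed, version).
* Ensemble default sizes (10 000 verification, 20 000 full-range,
  50 × 19 restricted) are the package's desk-scale choices; curves are
  smooth well below these sizes and all are overridable.
* The mixed-model optimizer tries L-BFGS then BFGS, prefers a
  converged fit, and otherwise uses the best finite fit with a logged
  warning; total failure raises with diagnostics rather than returning
  silently.
* Shortest-path tie detection in the brute-force test oracles uses a
  1e−9 tolerance; continuous random weights make exact ties
  vanishingly unlikely, and integer (hop) arithmetic is exact.

## Known limitations

* The network model is static; it cannot speak to rewiring or
  compensation dynamics.
* Trajectory coefficients are on internal standardized transformed
  scales and are not comparable to coefficients fitted by other
  machinery on other scales; only signs, exclusions and recovered
  structure are contractual.
* The betweenness family omits explicit zero inflation; with the
  log1p working scale this is adequate for sign/recovery contracts but
  not for calibrated zero-probability estimates.
* Empirical coefficient values from the source system are not
  reproduced here; the pipeline accepts real edge-list/attribute CSVs,
  but all validation is against synthetic ground truth.
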