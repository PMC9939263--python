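# agesocnet

Does individual social ageing scale up to reshape the structure of
animal societies? In many group-living species — rhesus macaques are
the motivating system here — females interact with fewer partners as
they age and concentrate their grooming on close kin, yet group-level
network structure often shows no detectable demographic signal.
`agesocnet` packages the computational machinery for studying this
question: a kin-structured, age-stratified random-network simulator, a
weighted grooming-network metric suite, a synthetic longitudinal
grooming-data generator with known ground truth, and hierarchical
models for within-individual age trajectories and global network
structure.

It is aimed at behavioural ecologists and network scientists who want
to (a) simulate how age-dependent linking probabilities shape network
topology, (b) ask when demographic effects on networks are
statistically detectable at realistic sample sizes, and (c) validate
longitudinal social-ageing analyses against data with known generating
parameters.

## The model

A group of *n* = 50 females is partitioned into 10 kin groups of 5.
Each network draws the number of old individuals
`n_old ~ Uniform{0,…,50}`, assigns age and kin labels by independent
random permutations, and links each dyad independently:

    P(edge between i and j) = p[type(i, j)]

where the dyad type is the age-class pair × kinship, with default
probabilities (0.33, 0.02, 0.37, 0.05, 0.27, 0.08) for
old/old kin, old/old non-kin, old/young kin, old/young non-kin,
young/young kin, young/young non-kin — empirical estimates from
macaque grooming networks. A closed form gives the expected mean
degree given `n_old`; at the extremes, 4.68 (all young) and 2.22 (all
old).

The analysis side decomposes each female's age into her mean across
observed years (between-individual) and her deviation from it
(within-individual), and fits mixed models of each network metric with
random intercepts for individual, group, year and network and a random
within-individual age slope — see `docs/methods.md` for families,
transforms and conventions.

## Worked example

```python
import numpy as np
from agesocnet import abm, experiments

# verify the simulator reproduces its input linking probabilities
table = experiments.run_verify(n_reps=10_000, seed=11)
print(table.round(4).to_string(index=False))
```

```
         dyad_type  input_probability  realized_mean  abs_deviation
       old_old_kin               0.33         0.3283         0.0017
    old_old_nonkin               0.02         0.0196         0.0004
     old_young_kin               0.37         0.3703         0.0003
  old_young_nonkin               0.05         0.0499         0.0001
   young_young_kin               0.27         0.2729         0.0029
young_young_nonkin               0.08         0.0802         0.0002
```

Each row compares an input dyad-type linking probability with the mean
proportion of such dyads actually linked across 10 000 simulated
networks — agreement to ~1e−3 confirms the generator is drawing edges
as specified.

```python
# demographic gradient: binned curves over the full range
reps, binned = experiments.run_fullrange(n_reps=20_000, seed=101)
print(binned[["bin_mid", "mean_degree_mean", "diameter_mean",
              "transitivity_mean"]].iloc[[0, 9, 19]].round(3).to_string(index=False))
```

```
 bin_mid  mean_degree_mean  diameter_mean  transitivity_mean
   0.025             4.626          5.331              0.096
   0.475             3.662          6.612              0.094
   0.975             2.293         10.764              0.114
```

Mean degree falls monotonically as networks age, diameter rises with
an accelerating trend (most of the increase arrives above ~50% old),
and transitivity barely moves below 80% old — so demographic effects
on structure are strongly nonlinear, and hardest to detect exactly
where real populations live (3–19% old). The restricted-range
experiment (`experiments.run_restricted`) makes that point directly:
with 19 networks confined to proportion old 0.04–0.20, per-bout trend
slopes scatter across both signs and most single-bout regression
intervals straddle zero.

The synthetic pipeline runs the full analysis end to end on generated
data with logged ground truth:

```python
result = experiments.run_synthetic_pipeline(seed=7, responses=("degree",))
print(result["estimates"]["degree"].coefficients.round(3).to_string(index=False))
```

```
             term  estimate  ci_low  ci_high
        Intercept     1.516   1.378    1.653
C(rank)[T.medium]     0.190   0.103    0.277
  C(rank)[T.high]     0.258   0.160    0.356
      delta_age_z    -0.059  -0.111   -0.006
    average_age_z    -0.092  -0.130   -0.053
```

The negative `delta_age_z` coefficient (95% interval excluding zero)
recovers the generating within-individual partner decline on the
standardized log1p scale; positive rank effects reflect the
generator's rank-dependent tie propensities.

A CLI mirrors these entry points:
`agesocnet verify|simulate|restricted|sensitivity|synth|pipeline --help`.

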