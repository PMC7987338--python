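# silverback

Association networks, permutation inference, and life-history models for
studying the consequences of **maternal loss in cohesive primate groups**
— built around the sampling design of long-term mountain-gorilla
(*Gorilla beringei beringei*) monitoring, where behaviour is recorded as
instantaneous focal scans and demography as dated life events.

The scientific question: when an immature gorilla (2–8 years old) loses
its mother, does it suffer the survival, reproductive and social costs
documented in most social mammals — or do relationships with other group
members (the dominant male, siblings, age-mates) buffer the loss?

The package is aimed at behavioural ecologists who want to run this
inference chain end-to-end, and at methodologists who want to probe its
statistical properties on synthetic data with known truth.

## What it implements

* **Synthetic study generator** (`simulate_*`): groups, maternal-loss
  incidents, latent per-scan dyadic association probabilities, 10-minute
  focal scans cycling through a shuffled group list, Siler-distributed
  lifespans with optional orphan hazard effects, logistic dispersal.
* **SRI networks** (`build_paired_networks`, `node_metrics`): weighted
  association networks per incident for the 6-month pre/post windows,
  edges by the Simple Ratio Index
  `SRI(A,B) = x_AB / (n_A + n_B)` — the proportion of focal scans of
  either member in which the pair associated — with the strict
  \>12-scans-in-both-windows inclusion rule and mother exclusion;
  normalized binary degree, weighted degree and eigenvector centrality.
* **Node-label permutation inference** (`run_permutation_test`): mixed
  model of the per-node metric change on orphan status, age, the
  initial-value deviance and a spline in sampling effort, referenced
  against 10,000 thinned within-incident label swaps; two-tailed
  `P_null = 2 · #{null t beyond observed} / N`.
* **Dyadic relationship-change models** (`fit_all_immature_model`,
  `fit_orphan_only_model`, `fit_adult_male_model`): mixed models of
  per-dyad SRI change with partner age-sex class (reference: dominant
  male), age-mate, sibling and paternity effects.
* **Survival models** (`fit_cox_ph`, `fit_siler_bayes`, `compare_dic`):
  Cox proportional hazards with the orphan class as a time-varying
  covariate (episode splitting, Efron ties), and a Bayesian survival
  trajectory analysis with the five-parameter Siler bathtub hazard
  `h(x) = a0·e^(−a1·x) + c + b0·e^(b1·x)`, three covariate structures
  compared by DIC.
* **GLMs** (`fit_female_dispersal`, `fit_age_first_birth`, …): binomial
  models of natal dispersal and first-offspring infant survival, a
  Gaussian model of `sqrt(age at first birth − 8)`, and the descriptive
  dominance-attainment summary.

## Worked example

```bash
python examples/03_network_position_permutation.py
```

```
149 immature records (28 orphans) from 19 incidents
orphan effect on weighted-degree change: 0.151 +- 0.014 (t = 11.13, model p = 0.0000)
permutation P_null = 0.0000 (1000 label sets, thinned every 100 swaps)
```

The generator's default conditions mirror the study population: 19
maternal-loss incidents, 28 orphans among ~150 immatures, and ~145 focal
scans per individual per 6-month window.  Under the default orphan
effects (largest latent boost toward the dominant male), orphans gain
weighted degree relative to non-orphan immatures in the same networks
(+0.151 on the max-normalized scale), and the permutation test flags the
gain as incompatible with random label assignment (`P_null < 0.001`).

The `examples/` directory has one short script per capability: study
simulation, network construction, permutation inference, dyadic models,
survival models, dispersal GLMs.

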