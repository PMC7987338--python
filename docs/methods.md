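# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of the package. Everything
quantitative stated here is computed by the test suite or the example
scripts; nothing is asserted that the code does not itself measure.

## The observational design being emulated

Habituated gorilla groups are monitored daily; behaviour is collected by
50-minute focal follows with an instantaneous scan every 10 minutes
recording all group members within 2 m of the focal and all members in
affiliative physical contact. Observers cycle through a randomly ordered
list of group members, which equalizes sampling effort. Association data
are therefore *frequencies* of joint records, not durations.

A maternal-loss incident is the death (or permanent transfer — the
network consequences are identical, and the generator treats both as
removal) of a mother leaving at least one offspring aged 2–8 years in
the group. Orphan classes by age at loss: infant [2, 4), juvenile
[4, 6), subadult [6, 8); analyses that merge juveniles and subadults use
`juv_subadult`. Ages are decimal years of 365.25 days; dates ISO-8601.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions, not tuning knobs.

* **Scale.** 19 groups of 12–18 members, one incident each, giving ~28
  orphans and ~120 non-orphan immatures — the scale of the real analysis
  sample. Focal effort is 12 scans/day per group over 183-day windows;
  cycled through a ~15-member group this yields ~145 focal scans per
  individual per window, matching the reported mean (144.8). A
  group-level rate of 24 scans/day would double that, which is why 12 is
  the default.
* **Latent associations.** Each dyad has latent per-scan probabilities
  (p_proximity, p_contact) with contact ≤ proximity; scans are
  independent Bernoulli draws given the focal, so the SRI is an unbiased
  estimator of the latent probability and additive latent effects appear
  additively in SRI changes. Dyad-level heterogeneity is a Beta draw
  (concentration 40) around class-pair means; the mother–offspring mean
  is set to the observed time budgets (0.39 proximity, 0.13 contact),
  other pairs range 0.03–0.13 with a +0.03 age-mate elevation among
  immatures. No across-scan dependence is modelled: the real data give
  no dependence structure to copy, and independence is what makes the
  SRI's expectation interpretable.
* **Maternal loss.** The post-loss latent set removes the mother and
  adds per-class boosts to orphan dyads (additive on probability, so
  they translate one-to-one into expected SRI changes): partner-class
  boosts, an age-mate boost, and sibling-by-class boosts, with contact
  receiving `contact_scale` (default 0.25) of each boost. All-zero
  boosts define the null generator. The default (study-condition)
  configuration gives the dominant male the largest boost, consistent
  with the direction of the published findings.
* **Demography.** Death ages are Siler draws conditional on survival
  through the post-loss window (so networks stay intact); orphan classes
  can carry proportional-hazard shifts. The incident mother is an
  established female (age 20–28) with possible prior offspring in the
  group, so orphans can have adult maternal siblings — without this the
  kinship terms of the adult-male model would be structurally empty.
  Paternity is known for ~60% of immatures; the father is the dominant
  male ~70% of the time.
* **Seeding.** One global integer seed; every generator derives an
  independent substream keyed by stable CRC32 hashes of (module, entity),
  so adding a group does not perturb another group's stream and all
  outputs are byte-reproducible.

## Networks and node metrics

SRI uses the sum of the two members' focal-scan counts as denominator —
with one focal per scan, joint-focal scans cannot occur, so this is the
plain simple-ratio dialect. Inclusion requires strictly more than 12
focal scans in *both* windows (literal reading of the rule); windows are
183-day calendar intervals with the loss day assigned to the post
window; orphans' mothers are excluded from both periods so the node sets
match. An incident whose orphan misses the scan threshold is dropped as
inadequate, as is an incident with no non-orphaned immature peer.

Binary degree, weighted degree and eigenvector centrality are each
normalized by the maximum over all nodes of the network (not only
immatures), mirroring eigenvector centrality's own max-normalization.
Eigenvector scores come from the leading eigenvector of the weighted
adjacency over non-isolated nodes (dense symmetric eigendecomposition;
isolated nodes score 0; entries taken in absolute value since the Perron
vector is sign-arbitrary); a power-iteration oracle verifies them to
1e-8 in the tests.

## Change model and permutation inference

Per-node change records carry delta = post − pre for each metric, plus
the *deviance* covariate: the node's pre-loss value minus the mean
pre-loss value over immatures in the same network. The model is a linear
mixed model: delta ~ orphan + age + deviance + s(total scans), random
intercept per incident. The smooth is a cubic B-spline basis (df = 4,
quantile interior knots, first basis function dropped against the
intercept); a penalized-GAMM smoother is deliberately not replicated —
the inference rides on the orphan term, not the smoother. Near-dependent
design columns (e.g. spline columns at degenerate sampling spreads) are
pruned by a singular-value screen rather than fitted at unbounded
variance.

The permutation null swaps orphan labels between immatures within the
same incident: a chain of single random swaps, thinned (default every
200th swap, 10,000 emitted sets), conserving per-incident orphan counts
by construction. For the per-set statistic, the variance components are
estimated once from the *orphan-free* model and frozen; each emitted
label set is then scored by GLS under that fixed covariance, and the
observed statistic entering `P_null` is computed by the same route.
Estimating the covariance without the labels keeps the null exactly
exchangeable and makes 10,000 refits affordable; the full mixed-model
fit (estimate, SE, t, parametric p) is reported alongside. `P_null` is
two-tailed with strict inequalities; at an exact median tie both doubled
tails are evaluated and the larger reported, capped at 1.

### Calibration caveat (a finding, not a bug)

On record-level data where labels are genuinely exchangeable within
incidents, `P_null` is uniform (KS p ≈ 0.3 over 200 replicates — tested).
Through the *full* chain under the null generator it is not, and the
mechanism is instructive: (i) the deviance covariate shares SRI sampling
noise with the change score, so its fitted slope absorbs
regression-to-the-mean; (ii) orphan status correlates strongly with
deviance (r ≈ −0.6) because orphans' mothers are excluded from the
networks while non-orphans' mothers are nodes carrying the strong
maternal edge. Jointly these bias the observed orphan statistic negative
(mean t ≈ −1.6 under the null) while permuted label sets — which cannot
reproduce the observed label–deviance correlation — stay centred at
zero. Raw changes are exactly label-symmetric (within-incident mean
difference ≈ 0); removing either coupling (equalizing the maternal bond,
or dropping the deviance covariate) removes the bias. The package keeps
the published model and documents the consequence: for the positive
orphan effects the method is used to detect, the bias is conservative.
The corresponding calibration test in `tests/test_acceptance.py` asserts
exact uniformity and is expected to fail under the default maternal time
budget; the companion test asserts and explains the bias.

## Dyadic models

One record per (immature, partner) dyad per association type, with
delta SRI, partner age-sex class at the loss date (dominant male,
subordinate adult male, adult female, blackback, subadult male/female,
juvenile, infant; reference always the dominant male), maternal-sibling
flag (shared known mother), age-mate flag (strictly < 2 years age
difference), paternity flag (NaN when unknown), and the dyad's mean
focal-scan count. Mother dyads and non-orphan-with-orphan-partner dyads
are excluded. Contact and proximity are always fitted separately.

All three models are linear mixed models with the B-spline effort smooth
and normal-based p-values: the all-immature model adds orphan × class;
the orphan-only model adds age-mate, sibling and class × sibling; the
adult-male model (known paternity only) uses dominance, sibling,
paternity and dominance × sibling — no dominance × paternity term, which
is collinear where the dominant male sires most offspring. Random
structure follows the design: incident (or group) intercept plus
variance components for immature and partner identity; the printed
"(Group|ID_O)" shorthand is realized as orphan-within-group intercepts.
If a variance component is unidentifiable at small n (REML surface
sending it to infinity), the structure is reduced one component at a
time with a warning; empty interaction cells are dropped from the fixed
design rather than estimated.

## Survival models

Records are left-truncated, right-censored age intervals: analysis time
starts at age 2 (younger infants cannot survive maternal loss, so orphan
status is undefined below 2); orphans enter at their age of loss for the
Bayesian fits; deaths before 2 are excluded; censoring is at last
monitoring. The Cox model re-expands everyone from age 2 with the orphan
class as a time-varying covariate via episode splitting (a zero-dummy
episode [2, loss) and a class episode [loss, exit)); fitting is
lifelines' Efron-tie Newton solver tightened to 1e-11, which the tests
hold to a brute-force partial-likelihood oracle at 1e-6 on tie-free
small datasets; monotone-likelihood draws are flagged as separation.

The Bayesian trajectory analysis uses the Siler likelihood
`L = Π h(exit)^event · S(exit | entry)` with three variants: (a) no
covariates; (b) one proportional log-hazard shift per orphan class;
(c) per-class log-scale effects on all five Siler parameters. Priors:
half-normal (scale 1) on a0, c, b0, half-normal (scale 2) on a1, b1,
N(0,1) on covariate effects — weakly informative defaults in hazard
units of 1/years. Sampling is an emcee ensemble (≥ 2·dim+2 walkers,
differential-evolution moves, 50% burn-in, thin 2) over the log of the
positive baseline parameters (Jacobian folded into the prior), started
around a bounded MAP; split-R-hat > 1.1 flags the DIC as unreliable.
DIC = mean posterior deviance + pD with pD = mean deviance − deviance at
the posterior mean; deltas are differences of unrounded DICs. With
truncation at age 2 the infant parameters (a0, a1) are weakly identified
and their posteriors lean on the prior — their wide intervals are
honest, not a defect.

Default lifespan parameters (a0 = 0.35/yr, a1 = 1.1/yr, c = 0.015/yr,
b0 = 0.0025/yr, b1 = 0.10/yr) give high infant mortality decaying over
the first years, a low adult plateau, and senescence from the thirties —
a great-ape-like schedule.

## GLMs

Dispersal and first-offspring survival are binomial-logit GLMs (IRLS,
deviance tolerance 1e-10, Wald z with normal-based two-sided p —
consistent with the printed statistics, e.g. z = 2.653 → p = 0.008);
coefficients beyond ±15 on the link scale are flagged as separation.
Age at first birth uses the response `sqrt(age − 8)` (8 years is the
earliest recorded first birth; the square root symmetrizes the skew) in
a Gaussian GLM, which equals OLS on the transformed response. The
package ships the class-level dispersal counts reconstructed from the
published percentages and sample sizes (12/32, 6/11, 6/8 females;
15/40, 11/13 males); on this saturated design the logistic MLE has a
closed form (log-odds differences; SEs as square roots of summed
reciprocal cell counts) that the tests use as an oracle. Dominance
attainment is a descriptive per-class proportion over males observed in
the population to at least age 23, requiring one tenure of ≥ 6
consecutive months; no test is attached, matching the deliberate
abstention at these sample sizes.

## Problem sizes used in the validation suite

The calibration and recovery experiments run at the study's scale where
that scale is part of the claim (19 incidents, 28 orphans, ~110
non-orphans for permutation power; 500 lifespans for Siler recovery) and
at reduced replication elsewhere: 200 replicate studies for P_null
uniformity, 50 for permutation power and dyadic recovery, 20 + 10 for
Siler coverage and DIC selection, with 150 permutation sets (thin 20)
per calibration replicate and ~900-step ensembles per MCMC fit. The
package defaults remain 10,000 sets / thin 200 and 1,500-step ensembles.

## Limitations

* Birth-date uncertainty (±90-day accuracy flags) is carried in the
  roster but not propagated into the survival likelihoods; the cited
  Bayesian framework supports age imputation, this implementation takes
  birth dates as given.
* The generator models no ranging, fission, inter-group encounters, or
  paternity genetics beyond a known-father label; dispersal out of the
  monitored population is censoring.
* Latent associations are scan-independent; real focal data have serial
  dependence within follows, which would widen (not bias) SRI sampling
  distributions.
* The permutation design's initial-value endogeneity (above) is a
  property of the published model that synthetic truth makes visible;
  conclusions drawn from positive observed effects are conservative
  under it.
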