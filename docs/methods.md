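# Methods

This note documents the models, defaults and numerical choices behind
`fosnet`, and what the synthetic-data validation does and does not establish.

## Behavioral indices and effect sizes

D1 for one trial is `(tNO − tFO) / (tNO + tFO)`; the cumulative D2 applies
the same ratio to exploration times summed over trials 1..k, so the final D2
weights trials by exploration time and damps single-trial noise. An animal
enters downstream analyses only if its final D2 is strictly above chance
(> 0). A trial (or cumulative prefix) with zero total exploration yields a
*missing* index, never 0: silently mapping 0/0 to 0 would push animals toward
exclusion, so missing values propagate and are logged.

Effect sizes follow the conventions of small-sample behavioral work:

* **ω²** from the one-way ANOVA decomposition,
  `(SS_b − df_b·MS_w) / (SS_t + MS_w)`; labels: < 0.01 small, ≥ 0.14 large,
  medium between (the medium band is closed downward at 0.01; label
  boundaries are closed on the larger-effect side throughout).
* **Hedges g**: pooled-SD Cohen's d times `J = 1 − 3/(4·df − 1)`;
  |g| ≤ 0.2 small, < 0.5 medium, ≥ 0.5 large.
* **Cliff's δ** by exhaustive pair enumeration;
  |δ| < 0.147 none, ≥ 0.147 small, ≥ 0.33 moderate, ≥ 0.474 large.

Regional activation is normalized per condition as
`value / mean(group, region) × 100`, so every (group, region) cell has mean
exactly 100. The transform is monotone within each cell, hence rank
statistics downstream are unchanged; it matters only for cross-group
displays and for the path model's input scale. It is idempotent.

## Co-activation networks

For each condition, pairwise average-rank Spearman correlations are computed
across animals (≥ 4 required; rows with missing values are dropped and
logged). The default two-tailed p uses the t approximation
`t = ρ·√((n−2)/(1−ρ²))`; with 6–8 animals this is coarse, so an exact
permutation p over all n! animal orderings is available for n ≤ 9
(`p_method="permutation"`). The default remains the t approximation for
comparability with standard correlation software. A constant region has no
rank variance; its pairs are recorded as *undefined* (never as ρ = 0) and are
excluded from both the edge set and the possible-pair count.

Edges keep pairs with p strictly below α (default 0.05) and carry the signed
ρ as weight. **No multiple-testing correction is applied across the pair
matrix** — the convention of the c-Fos connectome literature this package
follows; with ~400 pairs per matrix, individual edges must therefore be read
as descriptive, and all inference here is at the whole-network level
(permutation tests, null ensembles), which is unaffected by the per-edge
error rate.

### Metrics

Distance-based metrics use absolute weights with edge length `1/|ρ|`, so a
|ρ| → 1 edge has length 1 and every inverse distance lies in [0, 1]. Edge
sign is preserved in the data model and consumed only by the edge-composition
(positive/negative proportion) analysis. Strength is Σ|ρ| over incident
edges — a signed sum would let negative edges cancel positive ones and break
the reading of strength as centrality. Global efficiency is the mean inverse
shortest-path length over ordered pairs (disconnected pairs contribute 0);
global clustering is the transitivity of the binarized graph; betweenness
counts shortest paths with fractional credit for ties, unnormalized.

Louvain runs on absolute weights (a `binarize` option exists; weighted is the
default) at a caller-chosen resolution, with the node-order shuffling seeded
for reproducibility. The reported Q is always evaluated at resolution 1 on
the final assignment so partitions from different resolutions are comparable.
The resolution is chosen by bootstrap stability: animals are resampled with
replacement *within group* (the biological replicate is the defensible
resampling unit), the network rebuilt, and Louvain run per candidate
resolution; the winner is the resolution whose modal module count (isolated
nodes excluded) recurs most often, ties broken toward resolution 1.

### Null models and hubs

The chance reference for one condition redistributes the observed
(ρ, p) value pairs uniformly over the off-diagonal positions (symmetrically,
diagonal kept intact, p moving with ρ so thresholding stays paired). Members
therefore preserve the value multiset and the exact thresholded edge count
while destroying which regions connect — the correlation-matrix analogue of
a density-matched random graph. A permutation-of-node-labels shuffle was
considered and rejected: it is a graph isomorphism, so every global metric of
every member would equal the observed value and normalization would be
vacuous. Normalized metrics are `raw / mean(metric over 100 thresholded
members)`; a ring lattice with matched node and edge counts (largest |ρ|
values placed on the shortest ring distances) is reported alongside as the
segregated extreme, with a small-world-style position
`(raw − random)/(lattice − random)` for efficiency and clustering.

Hub detection is a two-stage rule. *Candidates* are nodes at or above the
90th percentile of the observed node distribution on degree, strength, or
betweenness. A candidate is a *hub* only if that metric also exceeds the 95th
percentile of the null distribution of the **network maximum** of the metric
over the shuffle ensemble. The maximum-statistic form is deliberate: in a
perfectly homogeneous network every node ties at the 90th percentile and a
per-node null check inflates false hubs badly (betweenness of ring networks
exceeds per-node chance in over half of calibration runs), whereas the
max-statistic check controls the family-wise false-hub rate; calibration
simulations show ≤ 10 % false-hub seeds on homogeneous rings and ≥ 95 %
detection of a planted hub (24 nodes).

### Comparing conditions

Group networks are compared by **label permutation**: animals are pooled,
group labels permuted B times (default 100), both networks rebuilt, and the
metric difference recomputed; the add-one estimator
`p = (1 + #{|null| ≥ |obs|})/(B + 1)` avoids zero p-values. Two-tailed by
default, with a one-tailed option. Permutation is used for hypothesis tests
because it gives an exact exchangeability null at 6–8 animals per group;
animal bootstrap is reserved for stability questions (resolution selection).
Type-I calibration over 200 null replicates at n = 7/group, 24 regions lands
at ≈ 4 % rejections at nominal 5 %.

Edge densities are compared with a chi-square omnibus on the groups ×
{edge, non-edge} contingency (possible pairs exclude undefined correlations),
followed by pairwise 2×2 chi-squares Bonferroni-corrected over the number of
group pairs. Expected cells below 1 trigger a warning and the
continuity-corrected 2×2 variant.

## The Bayesian microcircuit path model

Model 1 is the recursive system given in the README (five paths, three
residual scales); model 2 keeps only the direct GC regression
`GC ~ MC + PV_GL + PV_H`. ("Direct-effects-only" is read as the single
outcome equation; the alternative reading — the full system with indirect
effects merely not computed — would have an identical likelihood to model 1
and make the model comparison vacuous.) Both are fully observed
linear-Gaussian systems, so the likelihood factorizes into independent
regressions and the joint posterior is the product of the per-equation
posteriors.

Inputs are centered and scaled **within group** before fitting (studies of
this microcircuit report standardized betas per condition; pooled scaling is
the documented alternative), so no intercepts are needed. Priors are weakly
informative and recorded with every fit: normal(0, 10) on coefficients,
half-normal(10) on residual scales. Sampling is blocked Gibbs: the
coefficient vector of each equation has an exact conjugate normal conditional
given σ, and log σ is updated by a stepping-out slice sampler targeting the
half-normal-prior conditional. Four chains with over-dispersed starts;
release settings are 1,000 warmup + 5,000 retained draws per chain, and the
test suite and acceptance script use 250 + 750, at which split-chain R̂ stays
below 1.01 on every parameter in 100-replicate calibration runs.

Derived quantities, all per posterior draw and standardized by the
sd(predictor)/sd(outcome) of the data as fitted:

* indirect effects `a2·b2` (MC→PV_GL→GC) and `a1·b1` (PV_H→MC→GC) —
  definitionally exact products of the component draws;
* totals `b1 + a2·b2` (MC→GC) and `b3 + a1·b1` (PV_H→GC). The three-path
  chain `a1·a2·b2` is reported separately and folded into neither total,
  since the two named indirect paths define the mediation hypotheses;
* an effect is "significant" when its central 95 % credible interval
  excludes zero;
* Bayesian R² for the GC equation: var(linear predictor) /
  (var(linear predictor) + σ²), averaged over draws.

Model fit and comparison: the posterior predictive p uses the
maximum-likelihood covariance discrepancy
`log|Σ(θ)| − log|S| + tr(S·Σ(θ)⁻¹) − p` between a sample covariance and the
draw's model-implied covariance (exogenous block fixed at its sample value),
with replicates of the observed sample size simulated per draw; PPP near 0.5
is a good fit, and calibration runs put true-model PPP inside [0.2, 0.8] in
well over 90 % of replicates. This moment-based discrepancy is sensitive to
structural misfit (an omitted path drives PPP to ≈ 0) but blind to
mean-preserving nonlinearity. DIC uses the posterior-mean-deviance form with
`p_D = D̄ − D(θ̄)`; WAIC and LOOIC come from the pointwise log likelihood of
the whole system (arviz, deviance scale), with unstable importance weights
(Pareto k > 0.7) reported as warnings.

Multigroup analysis fits a *free* model (independent coefficients per group)
and a *restricted* one (coefficients shared, residual scales group-specific)
and prefers the lower total DIC. Pairwise group comparisons difference the
standardized coefficient draws of two fits (subsampled without replacement to
a common length); a parameter is flagged when the 95 % CrI of the difference
excludes zero or a sign probability exceeds 0.95. Note that standardization
couples equations: a group difference in one GC path rescales the other
standardized GC-equation betas through var(GC), so selectivity claims should
be read per equation.

## The synthetic study

The generator produces what the analysis assumes the real assay produces,
with known ground truth:

* **Activation tables**: per animal, one standard-normal latent factor per
  module; region value `baseline·exp(loading·g·factor + ε)`,
  ε ~ N(0, noise_sd). Counts are log-normal (positive, right-skewed;
  the marginal family is immaterial to rank statistics), and group
  differences enter as *loading multipliers* — connectivity differences —
  because the network stage consumes correlations, not means. The default
  study mirrors the analyzed cohort: 29 hippocampal/parahippocampal regions
  in five axis modules (rostral, medial, caudal-dorsal, caudal-ventral,
  parahippocampal), groups NOR/DIST/25/50/75 with 8/8/7/7/6 animals, base
  loading 0.7, noise sd 0.4, and multipliers 0.75/1.05/0.95/1.15/0.85 so
  that co-activation is densest under intermediate similarity demand and in
  the mixed condition, sparsest for plain novel-object recognition and the
  highest-similarity condition. Baseline count 100 is arbitrary (no raw
  count magnitudes are published to match) and irrelevant after
  normalization.
* **Microcircuit tables** follow the model-1 structural equations on a
  standardized scale, with configurable path coefficients, residual sds and
  n; the generator's covariances were verified against independent
  path-tracing algebra at n = 10,000.
* **Behavior**: gamma-distributed total exploration per trial around a mean
  (default 30 s, cv 0.2), novel-object share `0.5 + bias/2` plus clipped
  normal noise.

What passing tests show — and what they do not: calibration and recovery on
these fixtures establish that the estimators are correct *under the model's
assumptions* (monotone latent-factor coupling, Gaussian path system,
exchangeable animals). Real immunofluorescence data add integer counts,
counting error, section-level artifacts, non-Gaussian tails and possible
confounding between groups; none of these are emulated, so the tests certify
the machinery, not robustness to those features.

## Numerical choices and degenerate inputs

* Seeds are explicit arguments everywhere; no global random state. The
  pipeline derives per-stage seeds from one master seed via
  `SeedSequence([master, stage_index])`.
* Strict inequalities where a rule says "above": edge p < α, inclusion
  D2 > 0, hub value > null cutoff.
* Permutation/exceedance comparisons use a 1e-12 slack so ties in |ρ| count
  as exceedances rather than falling to floating-point noise.
* Edgeless networks: efficiency and mean strength 0; Louvain returns
  singleton modules with Q = 0 and a warning; triplet-free graphs have
  clustering 0 (logged).
* α is accepted in (0, 1]; α = 1 disables filtering (every defined pair with
  p < 1 becomes an edge).
* Division hazards raise: zero group-region mean in normalization (names the
  cell), zero null-ensemble metric mean in normalization, zero variance in
  the one-sample t and in standardization.

## Known limitations

* The per-edge significance threshold is uncorrected (see above); edge-level
  claims are descriptive.
* The exact-permutation p is exhaustive and limited to n ≤ 9; beyond that
  only the t approximation is offered (a Monte-Carlo permutation p would be
  the natural extension).
* The path model assumes linear-Gaussian relations among fully observed
  variables; no latent variables, non-Gaussian likelihoods, or informative
  priors.
* The PPP discrepancy is covariance-based and cannot detect
  covariance-preserving misfit.
* With 6–8 animals per group, single-condition networks are high-variance
  objects; whole-network permutation tests and null-normalized metrics are
  the only quantities this package treats as inferential.
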