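# Methods

## The model

`geofgm` estimates the risk that a girl aged 0–14 in a clustered household
survey has undergone female genital mutilation/cutting (FGM/C), as a
function of individual covariates, community norms, geography and time.
For girl *i* living in region *s* at survey time *t*, the outcome
y_i ~ Bernoulli(p_i) with a structured additive predictor on the logit
scale:

    η_i = β0 + z_i'β + Σ_j f_j(x_ij) + f_year(t_i)
        + f_str(s_i) + f_unstr(s_i) + f_st(s_i, t_i)

* **z_i'β** — linear effects of categorical/binary covariates (mother's
  FGM/C status, urban residence, religion, education, wealth quintile),
  dummy-coded against stated reference levels, with diffuse N(0, 10⁴)
  priors.
* **f_j** — smooth effects of continuous covariates (girl's and mother's
  age, the ethnic fractionalization index, the community proportions of
  cut/supportive/religious-obligation mothers), modelled as Bayesian
  P-splines: B-spline expansions with a random-walk prior on the
  coefficients, density ∝ exp(−β'Kβ/2τ²), K = D'ᵣDᵣ.
* **f_str** — spatially structured region effect with an intrinsic Markov
  random field (ICAR) prior: conditional on its neighbours a region's
  effect is N(neighbour mean, τ_s²/N_s). This "borrows strength" across
  adjacent regions.
* **f_unstr** — iid N(0, τ_u²) region heterogeneity.
* **f_st** — a space–time interaction surface built as the row-wise
  Kronecker product of the region-indicator basis and the time P-spline
  basis. Regions are areal units, so the space margin is an indicator
  basis rather than a spatial spline; the resulting surface is exactly the
  region-by-year deviation field that per-year prevalence maps display.
* Every penalized-block variance τ² carries an IG(a, b) hyperprior with
  defaults a = 1, b = 0.0005.

Community covariates are computed per sampling cluster (the survey's
primary sampling unit, approximating a village or urban neighbourhood).
The ethnic fractionalization index is EFI = 1 − Σ_k s_k², one minus the
Herfindahl concentration of the cluster's ethnic-group shares: 0 for a
monoethnic cluster, approaching 1 − 1/n for n equally-sized groups.
The default convention is leave-self-in with unit weights (a mother counts
toward her own cluster's shares); a leave-one-out variant exists for
sensitivity checks because survey reports never state which convention
their community variables used.

## Estimation

Inference is single-chain MCMC with Pólya–Gamma data augmentation
(Polson–Scott–Windle): given ω_i ~ PG(1, η_i), every coefficient block has
an exact Gaussian full conditional

    β_b | · ~ N( P⁻¹ X_b'(κ − Ω η_{−b}),  P⁻¹ ),
    P = X_b'ΩX_b + K_b/τ_b²,   κ = y − ½,

and every τ² an inverse-gamma one, IG(a + rank(K)/2, b + β'Kβ/2). The
sampler therefore needs no step-size tuning and is exactly reproducible
from its seed. The PG(1, z) draws use Devroye's alternating-series
rejection sampler (exact; acceptance probability > 0.99), implemented
in-package and numba-compiled; the sampler's mean and variance are checked
against the closed forms E = tanh(z/2)/(2z) and Var(z=0) = 1/24 in the
test suite.

This conditionally-Gaussian Gibbs scheme is an implementation choice, not
a model change: an IWLS–Metropolis sampler targeting the same posterior
would differ only in Monte-Carlo error.

**Identification.** The predictor decomposition is unidentified without
constraints: the ICAR prior is improper (null space = constants), and the
random-walk priors leave constants (order 1) plus linear trends (order 2)
unpenalized. After every sweep each spatial block is recentred to mean
zero over regions, each fully-observed spline block to mean zero over
observations (a partition-of-unity basis makes this an exact constant
shift), and the interaction block over both margins — row means move into
the structured spatial effect, column means into the time smooth, grand
mean into the intercept. The posterior full conditionals themselves are
proper (the data precision X'ΩX is positive definite on each block), so
sampling then recentring is equivalent to sampling on the constrained
subspace while avoiding per-sweep eigendecompositions. A smooth term
observed on only part of the sample (an attitude item absent from one
survey wave) is *not* recentred: its level is identified by the likelihood
and shifting it into the global intercept would alter η on the
non-contributing rows.

**Defaults.** Cubic B-splines with 20 interior knots and a second-order
random-walk penalty (the conventional P-spline configuration; knot count
matters little because the penalty carries the fit); 20 000 iterations,
2 000 burn-in, thinning 50; coefficients initialized at 0 and τ² at 0.1.
All are configurable. Smooths of covariates with few distinct values
(e.g. community proportions in small clusters, or survey year) are
allowed but flagged; the penalty regularizes them.

**Missing covariates.** Two conventions are implemented. `drop`
(default): complete-case over every covariate the model uses. `zero`
(used by the pooled suites): rows missing a *smooth* covariate stay in
the likelihood and contribute a zero basis row to that term only — the
term is fit on the waves that measured the item while the rest of the
model uses all waves. Dropped-row counts are always reported.

## Outcome harmonization

Survey waves report daughters differently: eldest daughter only
(1998/2003-style), most recently cut daughter (2008-style), or all
daughters 0–14 (2014-style). `harmonize_outcome` maps each to one girl
row per reporting unit with y = 1 if cut. For the most-recently-cut rule
the youngest cut daughter proxies the latest cutting event; mothers with
no cut daughter contribute their eldest daughter with y = 0 (the waves'
girl files contain uncut girls, so the rule cannot discard them). Each
emitted girl record is treated as one observation in pooled analyses —
how the original analyses weighted mothers with several eligible
daughters is not documented anywhere, so the package states its choice.

## Assessment

* **DIC** = D̄ + pD with pD = D̄ − D(η̄), the plug-in deviance evaluated at
  the posterior mean of the *predictor* (well-defined under the
  sum-to-zero constraints, unlike raw-coefficient plug-ins). Negative pD
  is reported, never clipped. Lower DIC is better.
* **ESS** = N / (1 + 2Σρ_k) with autocorrelations truncated by Geyer's
  initial-positive-sequence rule. ESS (sampling precision) and pD (model
  complexity) are deliberately reported side by side and labelled, since
  summary tables in this literature sometimes conflate them.
* **POR** — posterior odds ratio: mean of exp(β) draws with equal-tail
  95% credible interval.
* **Significance maps** — a region is HIGH/LOW if the 95% credible
  interval of its spatial effect lies above/below zero, else NONSIG. The
  total (structured + unstructured) effect is classified by default —
  the structured/unstructured split is weakly identified while their sum
  is what the data constrain — with a structured-only flag.
* **Predicted prevalence** — logit⁻¹(η) draws at a stated covariate
  profile per (region, year). The default profile is the reference
  category for linear terms with smooth terms at their centred average;
  any explicit profile can be supplied, and recovery tests use the
  generator's reference profile.
* **Moran's I** with binary weights and a two-sided permutation test
  (999 permutations by default) screens for spatial autocorrelation;
  permutation inference is the defensible choice at 8 areal units.

## The synthetic-data generator

The generator emulates the structure the model assumes, at the scale of a
national DHS-style survey: 8 regions with the (documented, assumed)
contiguity of Kenya's pre-2010 provinces → clusters (10 per region per
wave by default) → 25 mothers per cluster → 1–4 daughters each (mean 1.3,
so one wave yields ≈2 600 girls). Ethnicities are drawn from
region-specific mixtures over five groups (driving real EFI variation),
mothers' cut status from region-varying rates between 0.15 and 0.75,
attitudes correlated with own status, survey weights log-normal(0, 0.3²).
The linear predictor uses configurable true effects: β(mother cut) = 1.5,
β(urban) = −0.4, documented nonlinear shapes for girl age (rising
logistic), mother age (declining linear), EFI (decline past 0.4) and
community prevalence (kink above 0.5), an ICAR-distributed structured
field (τ_s = 0.8), centred iid heterogeneity (τ_u = 0.3), a declining
time trend (−0.6 across the span) and a region-loading × scaled-year
interaction (amplitude 0.3). Wave-specific reporting rules and
wave-specific missing attitude items (both items in the 2003-style wave,
the religious-obligation item also in the 1998-style wave) are applied so
the harmonization and missing-data paths are exercised.

Every sampled mother has at least one daughter aged 0–14, which makes the
community covariates attached after harmonization *exactly* the ones that
generated η — deliberate, so covariate-construction and recovery tests
have exact ground truth. What the generator does **not** emulate:
within-cluster random effects beyond the shared community covariates,
informative sampling weights (weights are independent of the outcome),
realistic fertility or household structure, non-response, or any actual
Kenyan covariate distribution. Passing recovery tests therefore shows the
estimator recovers the model's own structure at survey scale — not that
real surveys satisfy that structure.

## Study sizes used by the tests and the reproduction script

Chosen so the whole suite and the reproduction script each run in minutes
on one CPU, as the package's own desk-scale defaults: the recovery fit
uses one full-size wave (~2 600 girls, 5 000 iterations, burn-in 500,
thin 5); the interval-calibration study uses 60 replicates of a reduced
design (4 clusters × 12 mothers per region, ~620 girls) generated from
exactly the fitted model — a coverage study generates from the model it
fits, otherwise logistic non-collapsibility attenuates the coefficients
being covered; the model-comparison studies use 20 replicates per arm.
At this reduced scale empirical 95% coverage ran 0.86–0.96 across seed
batches (≈0.90 pooled): mildly below nominal, a known small-sample
feature of short chains and n in the hundreds, which is why the test
asserts a three-binomial-SE band rather than a point value.

## Known limitations

* Single chain; convergence monitoring is by ESS only.
* The structured/unstructured variance split is weakly identified at 8
  regions; interpret the total spatial effect.
* Isolated regions get no structured effect (fixed at 0) — the intrinsic
  conditional is undefined for a region with no neighbours; the default
  8-region fixture is connected so this policy never triggers there.
* Design-based (Taylor-linearized) standard errors for the weighted
  descriptives are out of scope; the weighted tables are point estimates
  with unweighted n.
* Adjacency is supplied by the user (edge-list or BayesX-style `.gra`
  file); it is not derived from polygon geometry.
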