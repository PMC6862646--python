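# geofgm

Bayesian hierarchical geo-additive modelling of female genital
mutilation/cutting (FGM/C) risk among girls aged 0–14 in clustered
household surveys (DHS-style), for epidemiologists and survey
statisticians who need prevalence maps and covariate effects that respect
spatial dependence, nonlinear covariate effects and the surveys'
two-stage cluster design.

## The model

For girl *i* in region *s* at survey time *t*, y_i ~ Bernoulli(p_i) with

    logit(p_i) = β0 + z_i'β + Σ_j f_j(x_ij) + f_year(t)
               + f_str(s) + f_unstr(s) + f_st(s, t)

where z_i'β are linear effects (mother's FGM/C status, urban residence,
religion, education, wealth), f_j are Bayesian P-splines (smooth effects
of girl/mother age, the ethnic fractionalization index
EFI = 1 − Σ_k s_k², and community norm proportions), f_str is an
intrinsic-MRF (ICAR) structured spatial effect on the region adjacency
graph, f_unstr an iid Gaussian region effect, and f_st a tensor-product
space–time interaction. Variance parameters carry IG(1, 0.0005)
hyperpriors. Estimation is exact Gibbs sampling via Pólya–Gamma
augmentation; models are compared by DIC, effects reported as posterior
odds ratios (POR) with 95% credible intervals, and regions classified
HIGH / LOW / NONSIG by whether the spatial effect's credible interval
excludes zero. A synthetic-data generator reproduces the whole survey
structure (regions → clusters → mothers → daughters, wave-specific
daughter-reporting rules, wave-specific missing attitude items) with
known ground truth, so every stage is testable without restricted
microdata. See `docs/methods.md` for the full account.

## Worked example

```python
from geofgm import (single_year_config, simulate_survey, standard_suite,
                    run_suite, MCMCConfig, morans_i)

cfg = single_year_config(2014, seed=42, n_clusters_per_region=6,
                         n_mothers_per_cluster=15)
ds, truth = simulate_survey(cfg)                    # 925 girl records

crude = ds.records.groupby("region_id")["y"].mean() \
                  .reindex(cfg.graph.region_ids)
print(morans_i(crude.to_numpy(), cfg.graph, n_perm=999, seed=1))

members = standard_suite(ds)                        # models A, B, C
summaries, comparison, _ = run_suite(
    ds, cfg.graph, members,
    MCMCConfig(n_iter=2000, burn_in=500, thin=5, seed=7))
print(comparison[["model", "dic", "pd", "n_obs"]])
```

prints the DIC comparison of the nested suite — the normative-influence-
only model (A), the space-adjusted model (B) and the fully adjusted
model (C):

```
model         dic        pd  n_obs
    C 1031.159410 27.237581    925
    B 1069.589591 12.647305    925
    A 1094.143625  8.231461    925
```

The fully adjusted model fits best (lowest DIC, as expected on data
generated with spatial and covariate structure); `pd` is DIC's effective
number of parameters. Its POR table and regional classification:

```python
summ = summaries["C"][0]
print(summ.por_table.head(2))
print(summ.region_table)
```

```
       term      por  ci_0.025  ci_0.975
 mother_cut 4.667471  3.221863  6.800916
      urban 0.866663  0.562841  1.334413

    region_id      mean    q0.025    q0.975  class
      Central -0.218096 -0.660729  0.201877 NONSIG
        Coast  0.575839  0.021873  1.109640   HIGH
      ...
      Nairobi -0.816390 -1.462755 -0.106736    LOW
```

A girl whose mother was cut has 4.7 times the odds of being cut
(95% CI 3.2–6.8; the generator's true coefficient of 1.5 corresponds to
an odds ratio of 4.5). Coast and North Eastern are significantly
high-risk after adjustment, Nairobi significantly low-risk.

The same pipeline is scriptable from the shell:

```bash
geofgm simulate --seed 3 --out-dir runs/sim --single-year 2014
geofgm suite --data runs/sim/survey.csv --seed 7 --iters 2000 \
             --burn-in 500 --thin 5 --out-dir runs/suite
geofgm maps --run-dir runs/suite --out-prefix runs/maps
```

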