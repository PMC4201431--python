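# nmixtures

Dynamic *N*-mixture models for repeated counts of **unmarked** animals,
with the standard comparison estimators and the multimodel-inference
machinery around them.  The package is aimed at wildlife and
population ecologists analysing robust-design count surveys — several
sites, a few visits per season, more than one season — especially
before–after control–impact (BACI) experiments where a treatment is
applied between two sampling seasons and the question is whether it
changed abundance, recruitment or survival.

## What it estimates

Counts of unique individuals per visit, `n_itj`, are binomial thinnings
of a latent site abundance:

    n_itj ~ Binomial(N_it, p_itj)                       (detection)
    N_i1  ~ Poisson(lambda_i)  or  ZIP(lambda_i, psi)   (initial abundance)
    N_i,t+1 = Binomial(N_it, omega) + Poisson(gamma_i)  (survival + recruitment)

with log links on `lambda` (initial abundance) and `gamma`
(recruitment), logit links on `p` (per-visit detection), `omega`
(apparent survival per transition) and `psi` (zero inflation).
Covariates enter each parameter through compact formulas
(`"a + b"`, `"a*b"`).  The likelihood marginalises the latent chain
exactly up to a truncation bound `K` (stability-checked).

Alongside the core model the package implements, behind the same data
containers:

* single-season (closed) *N*-mixture models,
* the Huggins closed-population estimator with Horvitz–Thompson
  abundance,
* Cormack–Jolly–Seber survival with unequal occasion intervals
  (`phi^interval` scaling),
* a Poisson random-intercept GLMM on raw counts (Laplace
  approximation) as the relative-abundance comparator,
* AICc ranking, Akaike weights, model-averaged coefficients and
  predictions with Burnham–Anderson unconditional SEs,
* parametric-bootstrap chi-square goodness of fit (full-refit and
  plug-in modes), and
* a calibrated synthetic-study generator (counts *and* matched
  individual capture histories from the same latent truth), so every
  estimator is testable without field data.

## A worked example

Simulate one study from the calibrated default scenario (56 sites, 29
treated with nest boxes between two seasons, two visits per season,
mean detection ~0.17), then fit and compare two dynamic models:

```python
from nmixtures import (DynamicNMixtureModel, ModelSet, CJSModel,
                       simulate_study, study_scenario,
                       parametric_bootstrap_gof)

draw = simulate_study(study_scenario(), seed=3)
ds = draw["dataset"].center_covariates(
    ["snag_ba", "conifer_ba", "precip", "julian_day"])
K = int(ds.count_array().max()) + 100

fits = [DynamicNMixtureModel(
            ds, lam, "1", "year*precip + year*julian_day + height",
            mixture="ZIP", K=K).fit(starts=2, seed=3)
        for lam in ("snag_ba", "1")]
ms = ModelSet(fits)
print(ms.table())

ab08 = ms.average_mean_abundance(0)
ab12 = ms.average_mean_abundance(1)
print(f"2008 abundance/site: {ab08.value:.2f} (SE {ab08.se_unconditional:.2f})")
print(f"2012 abundance/site: {ab12.value:.2f} (SE {ab12.se_unconditional:.2f})")

gof = parametric_bootstrap_gof(ms.best, B=100, seed=3, refit=False)
print(f"bootstrap GOF p = {gof.p_value:.2f}")

cjs = CJSModel(draw["histories"], "constant", "year-dependent").fit(seed=3)
print(f"CJS 4-year apparent survival: {cjs.interval_survival()[1]:.3f}")
```

prints (AICc column elided)

```
                                               Model   K  ...     dAICc         w
0  lam(1) gam(1) omega(1) p(year*precip + year*ju...  11  ...  0.000000  0.833644
1  lam(snag_ba) gam(1) omega(1) p(year*precip + y...  12  ...  3.223356  0.166356
2008 abundance/site: 13.28 (SE 67.36)
2012 abundance/site: 8.39 (SE 7.54)
bootstrap GOF p = 0.18
CJS 4-year apparent survival: 0.253
```

Reading the output: the Akaike weights split support between the two
initial-abundance structures; the model-averaged 2012 abundance (8.4
animals per site, SE 7.5) is in line with the generating truth (~7),
while the 2008 estimate is wildly imprecise (SE several times the
estimate).  That imprecision is real, not a bug: with two visits and
per-visit detection near 0.17, first-season abundance and detection
trade off along a flat likelihood ridge, which is exactly why the
capture–mark–recapture comparators (more information per individual)
and the GLMM (relative abundance only) exist in the package.  The CJS
apparent survival over the 4-year transition (0.25 here) is the
sharper counterpart to the dynamic model's survival parameter.

A command-line front end wraps the same workflow
(`nmixtures simulate | fit | select | gof | cmr | glmm | run`); see
`nmixtures --help`.

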