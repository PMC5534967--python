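# twinliab

Liability-threshold twin analysis for ordinal phenotypes: familial
relative risks, maximum-likelihood polychoric correlations with the
multiple-threshold goodness-of-fit test, ACE/ADE variance-component
modelling with nested model comparison, and a broadened-phenotype
association power simulation — plus a synthetic twin-cohort generator so
the whole chain runs without access to raw cohort data.

## Who this is for

Behaviour-genetic and psychiatric-epidemiology analyses of twin data
often need to answer three linked questions about an ordinal diagnosis
such as depression (non-depressed / minor / major):

1. **Does the phenotype cluster in families?** Proband → co-twin
   relative risks (RR) by zygosity, with monozygotic (MZ) > dizygotic
   (DZ) clustering pointing to genetic influence.
2. **Are the diagnostic categories severity levels of one underlying
   dimension?** The *multiple-threshold model* posits a continuous,
   normally distributed latent liability discretised by ordered
   cutpoints; a χ² goodness-of-fit test compares observed co-twin
   contingency tables to those implied by the fitted bivariate-normal
   (polychoric) model.
3. **How much liability variance is genetic?** Structural twin models
   decompose liability variance into additive genetic (A), common (C)
   or dominance (D), and unique environment (E) proportions, using the
   expected latent correlations r<sub>MZ</sub> = a² + c² + d² and
   r<sub>DZ</sub> = ½a² + c² + ¼d², compared via likelihood-ratio χ²
   tests and AIC, with profile-likelihood confidence intervals.

A fourth module asks what a single liability continuum implies for
gene-mapping strategy: whether *broadening* the case definition with
subthreshold (minor) cases increases the power of a case-control trend
test for a liability-affecting variant.

## Worked example

```python
from twinliab import (preset_params, simulate_cohort, crosstab, symmetrize,
                      relative_risk, fit_polychoric)
from twinliab.variance_components import ModelSpec, fit_model, likelihood_ratio_test

# 1220 twin pairs, ages 50-92, AE liability model with a2 = 0.47,
# minor/major prevalences 8.98% / 2.05%
records = simulate_cohort(preset_params("aged", seed=42))

mz = symmetrize(crosstab(records, "MZ", "two"))
print(relative_risk(mz, proband_condition=1, cotwin_outcome=1).format())

fit = fit_polychoric(crosstab(records, "MZ", "three"))
print(fit.format(), fit.gof_p)

ae = fit_model(records, ModelSpec("AE"), compute_ci=True)
e = fit_model(records, ModelSpec("E"))
print(ae.estimates["a2"], ae.ci["a2"], likelihood_ratio_test(ae, e).p)
```

prints (one seed, exact values vary with the cohort draw):

```
MZ RR (depressed co-twin | depressed proband): 6.06 (3.96–9.27)
MZ polychoric rho: 0.63 (0.49–0.74)   GOF chi2=1.81 df=5 p=0.87
AE model: a2 = 0.62 (0.48-0.73), -2LL = 1816.93, AIC = 1822.93
AE vs E: chi2 = 59.22, df = 1, p = 1.41e-14
```

Read: a depressed MZ proband multiplies the co-twin's depression risk
about sixfold; the three-category table is consistent with a single
liability continuum (GOF p = 0.87, so the multiple-threshold model is
not rejected); and dropping the additive genetic component from the AE
model is strongly rejected. The a² point estimate from a single
643-MZ-pair draw is noisy (the generating value 0.47 sits just below
the profile CI here); the calibration of estimates and intervals is
checked over many replicates by the test suite and acceptance script.

## Command line

```bash
twinliab simulate --preset aged --seed 1 --out cohort.tsv
twinliab rr --input cohort.tsv
twinliab polychoric --input cohort.tsv
twinliab compare --input cohort.tsv --classification three
twinliab power --or 1.10 --n-reps 2000
twinliab pipeline --preset te --seed 1 --out results/
```

`pipeline` runs the full chain and writes four TSV tables (relative
risks, liability-model fit p-values, polychoric correlations, the
variance-component model ladder), JSON twins of each, and a run
manifest; reruns with the same seed are bit-identical.

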