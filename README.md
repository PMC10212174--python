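# dfle — regional dementia-free life expectancy and its correlates

`dfle` is a Python package for small-area analysis of **dementia-free life
expectancy (De-FLE)**: the expected remaining years at an index age (65 by
default) lived below a dementia-disability threshold, and its complement,
**life expectancy with dementia (DLE)**.  It targets epidemiologists and
health-services researchers who work with region-level counts — mid-year
populations, deaths, and counts of persons above a disability threshold
(e.g. Japan's "Degree of Independence in Daily Living for the Demented
Elderly" Level II+ from long-term care insurance claims) — and who want to
relate the resulting regional health expectancies to regional indicators.

## What it computes

**Sullivan method.**  For each region and sex, an abridged period life table
is built from central death rates m_x = D_x/N_x with the Chiang conversion
q_x = n·m_x / (1 + (1−a)·n·m_x) (a = 0.5, open interval q = 1, L = l/m),
and person-years are weighted by the cross-sectional disability prevalence
π_x = U_x/N_x:

    DFLE(x0) = Σ_{x ≥ x0} (1 − π_x) · L_x / l_{x0},   DLE = LE − DFLE.

People absent from the disability data count as healthy, so π's denominator
is the whole age-group population.  Across-region summaries report mean, SD,
quartiles, and the normal-approximation 95% CI of the mean.

**PLS regression.**  A from-scratch multi-response NIPALS PLS2 relates the
four responses (De-FLE and DLE, each sex) to the regional covariates:

* leave-one-out cross-validation yields PRESS(k) for k = 0…K_max, with each
  training fold re-standardized so nothing leaks from the held-out region;
* **Van der Voet's randomization test** compares each smaller model's
  held-out squared residuals with the PRESS-minimal model's; the selected
  model is the smallest k not significantly worse (α = 0.10), with exact
  enumeration of all 2ⁿ sign patterns when n ≤ 20;
* **VIP scores** (mean of VIP² = 1) drive a two-stage fit: variables with
  VIP < 0.8 after the first fit are dropped and the model re-selected and
  refit, producing loading/correlation tables and paired-component plot data.

**Synthetic data.**  Because claims databases are restricted, the package
ships a generator with known ground truth: latent regional factors
(urbanicity, socioeconomic, healthcare) drive covariates, Gompertz
mortality and logistic-in-age disability prevalence; counts are Binomial
draws, and the true De-FLE per region/sex is computed from the noiseless
rates through the same life-table/Sullivan code.

## Worked example

```python
import dfle

cfg = dfle.SimulationConfig(n_regions=120, seed=7)
ds = dfle.simulate_dataset(cfg)
res = dfle.run_analysis(ds.demography, ds.disability, ds.covariates, seed=7)

print(res.summary.set_index(["metric", "sex"]).round(3))
m = res.manifest
print(f"retained {m['n_retained']}/{m['n_covariates']} variables, "
      f"{m['stage2_selected_components']} component(s)")
print(res.pls.explained.round(3).to_string(index=False))
```

prints

```
                 n    mean     sd     q25     q50     q75  ci_low  ci_high
metric sex
le     female  120  23.516  0.520  23.172  23.525  23.843  23.423   23.609
dfle   female  120  19.561  0.815  18.993  19.604  20.048  19.415   19.707
dle    female  120   3.955  0.354   3.732   3.936   4.201   3.892    4.018
le     male    120  19.531  0.490  19.177  19.527  19.831  19.443   19.618
dfle   male    120  17.707  0.653  17.272  17.761  18.130  17.591   17.824
dle    male    120   1.823  0.222   1.687   1.823   1.961   1.784    1.863
retained 4/12 variables, 1 component(s)
 component  frac_x  frac_y
         1    0.87    0.85
```

Mean female De-FLE at 65 is 19.56 years (95% CI 19.42–19.71) out of 23.52
years of life expectancy, so 3.96 years are lived with dementia-related
disability; males live fewer total years (19.53) but also fewer with
disability (1.82).  The default generator links disability prevalence to the
socioeconomic factor only, and the analysis recovers exactly that: the
VIP filter keeps the four socioeconomic covariates and a single latent
component (explaining 85% of response variance) carries the association.

The same pipeline runs from the shell:

```
dfle simulate --out data/ --seed 7
dfle dfle --demography data/demography.csv --disability data/disability.csv --out he.csv
dfle run --config pipeline.yaml
```

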