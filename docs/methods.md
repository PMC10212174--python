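# Methods

## Life table

Abridged period tables are built per region and sex from one-year counts:
central death rates m_x = D_x / N_x (deaths over mid-year population), the
Chiang conversion q_x = n_x m_x / (1 + (1 − a) n_x m_x) with the fraction of
the interval lived by decedents a = 0.5 (configurable via the age schema),
q = 1 at the single open-ended interval, L_x = n(l_x − d_x) + a·n·d_x for
closed intervals, L = l/m at the open interval (constant-hazard tail), and
e_x = T_x / l_x.  The default schema is five-year groups 65–69 … 90–94 plus
95+, matching an age-65 index for older-population health expectancy; any
strictly increasing schema with one terminal open group is accepted.  No
smoothing or graduation is applied to the rates.  The a-fraction and
terminal age are documented assumptions, not reconstructions of any
particular national calculation program.  Numerical guards: Chiang's
conversion can exceed 1 when n·m > 1/a, so q is capped at 1; a zero rate at
the open interval is an error (the tail person-years would diverge);
expectancy is reported as 0 where l has reached 0.

Under a constant hazard m this construction gives e = 1/m *exactly* at
every age, which the tests use as a closed form alongside a
spreadsheet-style column-by-column oracle.

## Sullivan health expectancy

Prevalence is π_x = U_x / N_x with the whole age-group population as
denominator: absence from the disability (claims) data counts as healthy,
because De-FLE is a population metric, not a metric of the certified
subpopulation.  DFLE(x0) = Σ_{x≥x0} (1−π_x) L_x / l_{x0}; DLE = LE − DFLE
by construction, so the identity DFLE + DLE = LE holds to machine
precision.  Sexes are processed fully independently.  Regional summaries
use the SD with n−1 denominator, quartiles by linear interpolation between
order statistics, and the normal 1.96 multiplier for the CI of the mean —
with hundreds of regions the t and normal multipliers are
indistinguishable, and the normal form is what regional health-expectancy
tables conventionally print.  Missing cells are never imputed; a region
with any incomplete cell is excluded and counted in the run manifest.

## PLS2, PRESS, Van der Voet, VIP

The PLS is written from scratch (scikit-learn serves only as a test
oracle).  Both X and Y are standardized (column z-scores, n−1 SD); whether
to scale Y as well as X is genuinely open in this setting, and scaling both
keeps the four responses (De-FLE and DLE per sex, which differ several-fold
in SD) comparable inside one joint fit.  Components are extracted by
NIPALS: u initialised to the largest-variance Y column; w ∝ X'u (unit
norm); t = Xw; c = Y't/(t't); u = Yc/(c'c); convergence when the relative
change of t falls below 1e-10; p = X't/(t't); both blocks deflated by t.
The weight iteration is a power iteration on (X'Y)(X'Y)', so when two
singular values of the deflated cross-block nearly tie — routine for deep
components once Y is mostly exhausted — it converges arbitrarily slowly.
After 5 000 iterations the component is therefore resolved from its exact
fixed point: w = (X'Y)v with v the dominant eigenvector of the q×q matrix
(Y'X)(X'Y).  This is the same fixed point the iteration targets and keeps
deep components deterministic.  Sign convention: each weight column's
largest-magnitude entry is positive.  Coefficients B = W(P'W)⁻¹C' make
predictions linear in the standardized X.  Per-component explained
fractions are ‖t p'‖²_F/‖X₀‖²_F and ‖t c'‖²_F/‖Y₀‖²_F.

Cross-validation leaves out one region at a time, re-centres and re-scales
both blocks on the training fold (no leakage), and back-transforms the
fold-standardized prediction to the input scale before residuals are taken;
PRESS(k) pools squared residuals over all responses, and k = 0 is the
training-fold-mean model.  In the pipeline the Y passed in is already
globally standardized, so pooled residuals weight the four responses
comparably; per-response PRESS columns are also reported.

Van der Voet's test uses per-observation differences of summed squared
residuals d_i; the null distribution of C = Σd_i flips each sign
independently — enumerated exactly over 2ⁿ patterns when n ≤ 20, else by
Monte-Carlo draws with a required seed.  The two-sided p counts the
observed pattern in numerator and denominator, so p ∈ (0, 1].  Selection:
k_min is the smallest k attaining the minimum PRESS (ties broken toward
parsimony); the selected model is the smallest k ≤ k_min with p ≥ α.
α defaults to 0.10, the convention of the commercial PLS software family
used in the ecological studies this package mirrors; it is configurable.
The search is capped at K_max = min(p, n−2, 15) by default.  Note the sign
test reacts to *consistent* differences regardless of magnitude; with
hundreds of observations it is very powerful, which is the intended
behaviour of the reference procedure.

VIP_j = sqrt(p Σ_k SSY_k (w_jk/‖w_k‖)² / Σ_k SSY_k) with SSY_k the
Y-variance fraction of component k; mean VIP² = 1 identically.  The
two-stage fit selects components on all variables, prunes at VIP ≥ 0.8
(the conventional threshold, configurable), then re-selects and refits on
the survivors — selection order (select → prune → re-select) is one of two
defensible readings of the reference workflow and is the one implemented.
Loading/correlation tables report the Pearson correlation of every
variable and response with each score vector, plus paired-component
coordinates for correlation/loading plots.

## Synthetic generator

The generator emulates restricted region-level claims data.  Latent scores
Z ~ N(0, I) on three factors (urbanicity, socioeconomic, healthcare) drive
covariates X = ZΛ + ε (block loading matrix by default, noise SD 0.5),
log-mortality and prevalence log-odds.  Mortality is Gompertz,
m(x) = a·exp(bx) with a = 2.5e-5, b = 0.095 evaluated at group midpoints
(open group at start + 2.5), giving hazards rising from ~1.5%/year at 65–69
to ~26% at 95+; prevalence is logistic in age (intercept −16.2, slope 0.17
per year), ~1% at 65–69 to ~60% at 95+.  Females get a 0.64 multiplier on
the Gompertz level and +0.4 on the prevalence log-odds, reproducing the
familiar pattern: longer life, more disabled years.  With the default 5 000
persons per age group these choices give LE at 65 of ≈19.5 (male) / 23.5
(female) years with ≈1.8 / 4.0 years of it lived with disability —
magnitudes typical of published regional dementia-disability studies.  The
socioeconomic factor lowers prevalence (−0.25 log-odds per SD) and
mortality (−0.05 log-hazard per SD) by default, so better-off regions have
longer De-FLE; that is the structure recovery tests look for.

Counts are Binomial per cell — deaths with the one-year probability
1 − exp(−m), disability with π — so counts can never exceed populations.
The ground-truth De-FLE pipes the *expected* rates (expected deaths / N,
i.e. 1 − exp(−m), and π) through the production life-table and Sullivan
code, making recovery self-consistent: in deterministic mode the generator
emits exact (non-integer) expectation counts, and the pipeline recovers
the truth to machine precision; with sampled counts at population 10⁵ per
group the absolute De-FLE error stays below 0.1 years in ≈97% of cells.

What the generator does **not** emulate: the marginal distributions and
correlation structure of real national indicator sets, municipality-level
heterogeneity, migration, age-misreporting, or claims-coding error.
Passing recovery tests therefore demonstrates the correctness of the
estimators under the stated generating model, not robustness to real-data
pathologies.

A second, bare generator (`simulate_latent_pls`) produces latent-factor
regression data for exercising the PLS machinery alone: three factors,
twenty informative predictors with small measurement noise (SD 0.05, so the
informative block genuinely has the factors' rank and "three components"
is the true model order), response noise SD 0.5, optional pure-noise
predictors as ground-truth labels for variable-selection checks.  At
n = 200 the PRESS + Van der Voet procedure selects exactly three components
in ≈100% of replicates and the VIP filter removes essentially all
pure-noise columns.

## Pipeline

Municipal indicators are aggregated to regions by pooling numerators and
denominators and recomputing each ratio — never averaging municipal rates —
with errors for unmapped municipalities and zero pooled denominators.
Regions with any missing cell are excluded (logged, manifest-counted, and
regions_in = analyzed + excluded exactly); fewer than three complete
regions is an error.  Iteration is lexicographic in (region, sex), and all
randomness flows from one top-level seed, so identical config and seed give
byte-identical output files.  Artifacts: per-region health-expectancy and
summary CSVs, PRESS curve with Van der Voet p-values, stage-1/stage-2 VIP
tables, loading/correlation and explained-variance tables, paired-component
plot data, and a JSON manifest (versions, parameters, row accounting,
selected component counts).

## Problem sizes used in checks

The test and reproduction scripts run at desk scale: 12–50 regions for
recovery checks, 300–335 regions (the scale of the motivating national
study) for the end-to-end runs, 50 replicates for the component-selection
and VIP rates, Monte-Carlo randomization at 999–1 999 draws with exact
enumeration whenever n ≤ 20.  These sizes are the package's own choice of
a thorough-but-quick default; all of them are parameters.

## Known limitations

* No Sullivan variance (Jagger-style SE) per region; CIs are across-region
  summaries only.
* No cohort (incidence-based, multistate) health expectancy; the Sullivan
  estimate is a period, prevalence-based metric with its usual biases under
  changing incidence.
* No infant/young-age a-fraction conventions: the life table targets the
  older-population index-age use case.
* PLS variants (SIMPLS, kernel PLS) and bootstrap CIs on loadings are out
  of scope; randomization inference covers only model-order comparison.
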