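# oncotraj

Joint stochastic modelling of tumour growth, metastatic seeding and
cancer-patient survival.

Clinical routine data — visit-level tumour measurements, metastasis
counts and survival status — are usually analysed one process at a time:
growth curves here, survival models there.  `oncotraj` is for
biostatisticians and mathematical oncologists who want the three
processes in one likelihood.  It models a patient as a combined Markov
process **X**(t) = (S(t), N(t), D(t)):

* **S(t)** — deterministic tumour volume: exponential (S' = βS),
  Gompertz (S' = βS ln(K/S)), the Gyllenberg–Webb
  proliferating/quiescent/dead compartment model, or exponential growth
  with covariate-dependent rate β(t) = β₀ + μᵀ**Z**(t) (treatment,
  obesity);
* **N(t)** — metastasis count, an inhomogeneous Poisson process with
  intensity λ_N = m_basal + m_size √S(t) (volume-based) or
  λ_N ∝ A(t)^k · S'/S with A(t) the number of cell divisions
  (division-based);
* **D(t)** — survival, a first-jump-stopped Poisson process with hazard
  λ_D = d_size √S(t) + d_metas N(t).

The package provides

* an **exact simulator** (next-reaction inversion of cumulative
  intensities) with a clinical observation model: monthly visits, noisy
  sizes (S̃ = S(1+σ_S ε)), exact counts, exactly-observed deaths,
  censoring at 30 months, and registry-style missingness;
* the **marginal likelihood** of such records, with the unobserved
  metastasis jump times integrated out.  The m-dimensional survival
  integrals collapse exactly to powers of 1-D integrals (closed form
  for exponential growth, Clenshaw–Curtis quadrature otherwise); an
  independent nested-cubature route and a Monte-Carlo oracle validate
  them.  Missing sizes/counts are marginalised exactly
  (Chapman–Kolmogorov merging, finite sums at death rows);
* **inference**: multistart L-BFGS-B maximum likelihood on log-scale
  parameters, adaptive parallel-tempering MCMC with 80/90/95%
  credibility intervals, and AIC model selection;
* five ready-made study models `m1`–`m5` (exponential/volume-based,
  cell-division, Gompertz, Gyllenberg–Webb, treatment-effect) with
  generating parameters and log-scale bounds.

## Worked example

Recover a treatment effect from simulated visit records
(`examples/05_treatment_effects.py`):

```python
from oncotraj import StudyDesign, get_model, simulate_cohort
from oncotraj.infer import credibility_intervals, fit_mle, sample_posterior
from oncotraj.likelihood import CohortLikelihood

model = get_model("m5")                       # beta(t) = b0 - rho*treat + delta*obese
cohort = simulate_cohort(model, 250, StudyDesign(), seed=6)
cl = CohortLikelihood(model, cohort)
fit = fit_mle(model, cohort, n_starts=15, seed=7, likelihood=cl)
samples = sample_posterior(model, cohort, fit.log_theta_mle, seed=8,
                           n_iter=2000, n_temps=3, n_chains=1, likelihood=cl)
intervals = credibility_intervals(samples, levels=[0.95])
```

which prints

```
 parameter     true      MLE   95% credibility
      beta   -0.693   -0.693   (-0.693, -0.692)
       rho   -0.799   -0.799   (-0.800, -0.798)
     delta   -1.609   -1.609   (-1.611, -1.608)
   m_basal   -4.605   -4.438   (-4.772, -4.209)
    m_size   -6.908   -6.965   (-6.987, -6.822)
    d_size   -8.112   -7.893   (-8.113, -7.648)
   d_metas   -5.809   -8.163   (-8.876, -5.690)
```

All values are natural-log scale.  The growth parameters (β₀, the
treatment effect ρ, the obesity effect δ) are recovered to three
decimals because hundreds of size measurements pin them down; the
process rates carry honest statistical uncertainty, widest for d_metas,
which sits behind two layers of stochasticity.  Every generating value
lies inside its 95% credibility interval.

The other example scripts cover the growth laws
(`01_growth_curves.py`), cohort simulation and missingness
(`02_simulate_cohort.py`), the agreement of the analytic, quadrature
and nested-cubature likelihood routes (`03_likelihood_routes.py` —
relative spread ~1e-15), and AIC selection between the volume-based and
cell-division seeding models (`04_fit_and_select.py`).

## Command line

A thin CLI wraps the same calls:

```sh
oncotraj simulate --model m1 --n 500 --seed 1 --out cohort.csv
oncotraj loglik   --model m1 --cohort cohort.csv
oncotraj fit      --model m1 --cohort cohort.csv --starts 100 --seed 7 --out fit.json
oncotraj sample   --model m1 --cohort cohort.csv --fit fit.json --iters 50000 --out post.json
oncotraj select   --models m1,m2 --cohort cohort.csv
```

Cohorts are long-format CSV (one row per visit, empty cell = missing)
with a JSON provenance sidecar, or single-file JSON.

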