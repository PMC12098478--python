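# Methods

`oncotraj` implements a combined stochastic model of cancer-patient
trajectories: a deterministic tumour-growth law, an inhomogeneous-Poisson
metastasis counting process whose intensity depends on tumour size, and a
death process whose hazard depends on both.  This note records the model,
the numerical design and the choices made where the design was open.

## The combined process

For each patient the latent state is X(t) = (S(t), N(t), D(t)) on
t ≥ 0 (months since detection).

**Tumour growth S(t)** (volumes in mm³) follows one of:

* exponential: S' = βS, S(t) = S₀ e^{βt};
* Gompertz: S' = βS ln(K/S), S(t) = K exp(ln(S₀/K) e^{−βt}) with
  carrying capacity K;
* Gyllenberg–Webb: three compartments P (proliferating), Q (quiescent),
  R (dead) with P' = (b − r_out(M))P + r_in(M)Q,
  Q' = r_out(M)P − (r_in + μ_q)Q, R' = μ_q Q − d_clear R, where
  M = P+Q+R, r_in(M) = r/(M+m), r_out(M) = kM/(aM+1).  The tumour
  volume is S = P + Q by default — dead cells do not seed metastases —
  with an `include_dead` switch for S = P+Q+R.  Both conventions appear
  in the literature on this model; the default follows the biological
  argument, and tests exercise both.
* covariate-dependent exponential: β(t) = β₀ + μᵀZ(t) with
  piecewise-constant 0/1 covariates; in the treatment model
  μ = (−ρ, δ), so a treatment lowers the growth rate by ρ and obesity
  raises it by δ.  S(t) = S₀ exp(∫₀ᵗ β(s) ds) is continuous and
  piecewise exponential.

All patients start at the detection threshold S₀ = 0.065 mm³ (a 0.5 mm
sphere, πd³/6) with N(0) = N₀ = 0; by the Markov property and the
deterministic growth this loses no generality, and the constant time
shift from the single-cell origin (volume of a 0.01 mm sphere) is
available as `onset_time_shift`.

**Metastatic seeding** is an inhomogeneous Poisson process with one of
two intensities:

* volume-based: λ_N(t) = m_basal + m_size √S(t);
* cell-division-based: λ_N(t) = m_division A(t)^k S'(t)/S(t), where
  A(t) = (ln S(t) − ln S_cell)/ln 2 counts cell divisions since the
  single-cell origin.  Note the convention: the per-division rate is
  taken as the relative growth rate S'/S = ln2 · A′, which makes the
  cumulative intensity the exact closed form
  Λ = m_division ln2/(k+1) (A(t_b)^{k+1} − A(t_a)^{k+1})
  (= m_division β^{k+1}(t_b^{k+1} − t_a^{k+1})/((k+1) ln2^k) for
  exponential growth from the single cell).  An alternative convention
  divides by ln 2; the two differ only by a rescaling of m_division and
  are observationally identical.  Because λ_div is a perfect derivative,
  this cumulative is closed-form for *any* growth law.

**Death** is a first-jump-stopped Poisson process with hazard
λ_D(t) = d_size √S(t) + d_metas N(t); survival to t has probability
exp(−∫₀ᵗ λ_D).  The √S link (rather than S) keeps the hazard and the
seeding intensity numerically well-scaled across the five orders of
magnitude a growing tumour spans.

## Observation model

Visits occur on a fixed monthly grid until death or the 30-month end of
follow-up.  At each visit the tumour volume is observed with
proportional Gaussian noise, S̃ = S(1 + σ_S ε), ε ~ N(0,1) (log-normal
noise S̃ = S e^{σ_S ε} is available as an option), and the metastasis
count is observed exactly (a detection delay for metastases would be a
constant shift under constant growth and is absorbed).  Death is
observed at its exact time and recorded as a final row carrying only the
death indicator — the tumour is not re-measured at that instant, so the
death row has no size observation.  Censored patients simply end at the
last scheduled visit.

## Exact simulation

Trajectories are drawn with a next-reaction scheme: successive
unit-exponential increments E are inverted through the cumulative
intensity, t_{next} = Λ⁻¹(E), using closed-form cumulatives where
available and bracketed Brent root-finding (tolerance 1e-10) otherwise.
The death time inverts the integrated hazard along the realised
piecewise-constant count path.  Inversion is exact for unbounded
intensities, where thinning has no usable envelope (the exponential-law
intensity grows without bound).  Cohorts use per-patient substreams
spawned from one seed, so they are reproducible regardless of
parallelisation or order.

`mask_missing` emulates registry-style incompleteness: visits dropped
with probability p_visit_drop, size/count fields masked with their own
probabilities; a death row is never dropped and its indicator never
masked (when a row exists, survival status is known).

## Likelihood

Patient records are independent, and the Markov property factorises each
patient's likelihood over inter-visit intervals into

1. Gaussian (or log-normal) size-observation terms;
2. Poisson increment terms for the observed count increments m over an
   interval with cumulative intensity Λ: m ln Λ − Λ − ln m!;
3. marginal survival terms: the probability of surviving the interval
   given m unseen jumps is an m-dimensional integral of
   exp(−∫λ_D) over the ordered jump times, whose conditional density is
   m! Πλ_N(u_i)/Λ^m;
4. for the death interval, the death density λ_D(T_d, S(T_d), n+m) times
   the survival probability of (3).

**Rank-1 reduction (analytic path).** Since λ_D is linear in N with a
coefficient independent of the jump positions, the integrated hazard
along a path with jumps u_1 < … < u_m is
d_size∫√S + d_metas[n·Δt + Σᵢ (t_b − u_i)], and the conditional jump
times are i.i.d. with density λ_N/Λ.  The m-dimensional integral
therefore collapses *exactly* to

    P(survive | m) = exp(−d_size∫√S − d_metas n Δt) · J^m,
    J = (1/Λ) ∫ λ_N(u) e^{−d_metas (t_b − u)} du,

valid for every m.  For (piecewise-)exponential growth both integrals
are closed-form (expm1-stabilised); for Gompertz/Gyllenberg–Webb they
are computed by fixed high-degree Clenshaw–Curtis rules, vectorised over
all intervals of a cohort.  The identity is *verified*, not assumed: two
independent evaluations guard it in the tests —

* a direct nested cubature of the simplex integral (ordered mapping of
  the simplex to the unit cube, tensor Clenshaw–Curtis rule, p-adaptive
  degree doubling at relative tolerance 1e-8, integrated hazards from
  Chebyshev antiderivatives of √S), and
* a Monte-Carlo oracle that draws the conditional jump times by inverse
  CDF and averages exp(−hazard).

**Missing data** are marginalised exactly:

* missing size → the observation term is dropped (it marginalises to 1);
* missing count at an interior visit survived through → the visit is
  skipped and the flanking intervals merge (Chapman–Kolmogorov; a test
  verifies the merged value equals the explicit sum over the hidden
  intermediate count);
* missing count on a death row → finite sum of Poisson(m) × death
  density over m = 0..M_max, with M_max the largest count observed in
  the data (floor 5);
* missing count on a censored final row → the Poisson-marginal survival
  has the closed form exp(−d_size∫√S − d_metas n Δt − (Λ − JΛ))
  (Campbell's theorem), which equals the infinite sum the truncation
  approximates; a test checks the enumeration converges to it.

Impossible data under a parameter vector (e.g. observed metastases with
zero seeding rates) yield a −∞ log-likelihood sentinel rather than an
exception, so optimisers can recover.  All accumulation is in the log
domain.  Censored patients contribute Poisson + survival terms only.

## Inference

Parameters are positive, so all optimisation and sampling is on natural
logs inside box bounds (the treatment model ships the published
log-scale bounds; the others carry bounds of the same style).

* **MLE**: multistart L-BFGS-B (default 100 starts, log-uniform in the
  box; ftol 1e-12) over the compiled vectorised likelihood, with two
  refinements per start: an L-BFGS-B restart from the incumbent (clears
  a stale quasi-Newton Hessian) and a bounded Nelder–Mead polish —
  finite-difference gradients stall on the flat m_basal/d_metas ridge of
  the numeric-likelihood models, and the simplex step converges the last
  distance, as gradient-free refinement generally must for numerically
  integrated objectives.  A bounded dual-annealing fallback exists for
  rugged objectives.  Ties are broken by lowest objective, then start
  index.  σ_S is fixed at its known
  value during inference (its estimate is not part of the study design);
  adding it as a free parameter only requires listing it in
  `free_names`.
* **MCMC**: adaptive parallel tempering — a geometric temperature ladder
  (default 4 temperatures up to T=25; the scaled study uses 3), one
  Metropolis sweep per temperature per iteration with Haario-style
  running-covariance proposals and Robbins–Monro step-size adaptation
  towards 23% acceptance, and one adjacent-pair swap attempt per sweep.
  The first half of each chain is discarded as burn-in; central
  quantile intervals (80/90/95%) are nested by construction.
* **Model selection**: AIC = 2p − 2·max log-likelihood; candidates must
  be fitted to the same cohort; the ΔAIC table flags the minimum.

## Study parameterisation (synthetic-data defaults)

The generating values ship with the model registry; time unit months,
volumes mm³, rates per month:

| model | growth | free parameters (log-scale truth) |
|---|---|---|
| m1 | exponential (β=0.5) | β −0.693, m_basal −4.605, m_size −6.908, d_size −8.112, d_metas −5.809 |
| m2 | exponential (β=0.5) | β −0.693, m_division ln0.005≈−5.30, d_size −8.112, d_metas −5.809 |
| m3 | Gompertz (β=0.2, K=150 cm³) | β, K and the four m1 process rates |
| m4 | Gyllenberg–Webb (b=1, μ_q=0.05; d_clear=0.01, r=1, k=2, a=1, m=2 fixed) | b 0, μ_q −3.0, m_basal −3.0, m_size −2.3, d_size −4.6, d_metas −3.5 |
| m5 | exponential + covariates | β −0.693, ρ −0.799, δ −1.609 + the m1 rates |

Rationale: the exponential-family rates are the natural-scale values
implied by the treatment model's published log-scale parameter table and
give a realistic study — roughly 2 expected metastases and ~45%
mortality per 30 months.  The Gompertz growth parameters are the
mid-range values of the growth-curve illustrations (β=0.2, K=150 cm³).
The Gyllenberg–Webb growth uses the standard example parameter set
[b=1, μ=0.05, d=0.01, r=1, k=2, a=1, m=2]; because that model saturates
at volumes of order 10 mm³, its seeding and death coefficients are set
larger (m_basal=0.05, m_size=0.1, d_size=0.01, d_metas=0.03) so that a
comparable fraction of patients develop metastases and die — tiny
√S-coefficients would make the study uninformative.  σ_S = 0.1
throughout.

Treatment-model covariates: each patient is treated with probability
0.5, with a permanent treatment starting uniformly in the first 12
months; 30% of patients are obese throughout.  Keeping an untreated arm
and staggering the start times is what identifies ρ separately from β₀,
and it keeps the size-driven rates (m_size, d_size) identifiable —
under universal early treatment tumours stay small and those
coefficients barely act.

## Numerical choices

* Clenshaw–Curtis everywhere: 1-D adaptive rule doubles the degree until
  successive estimates agree to relative 1e-8 (absolute floor 1e-12);
  the cohort fast path uses fixed degree 32 (geometric convergence makes
  this ≲1e-12 for month-scale analytic integrands); the batched nested
  cubature uses per-dimension node counts {m=1: 32, 2: 16, 3: 12, 4: 10,
  ≥5: 8}, and the scalar adaptive version schedules 8→12→…→64 nodes with
  caps growing down in dimension.
* The Gyllenberg–Webb ODE is solved once per parameter vector (LSODA,
  rtol 1e-10, atol 1e-12) and re-interpolated by a cubic Hermite spline
  on 8193 points (error ~h⁴/384 < 1e-11), giving fast vectorised
  evaluation that the solver's segment-wise dense output cannot.
* Stable primitives: (e^x−1)/x via expm1 with a series branch below
  1e-8; damped seeding integrals keep all exponents bounded by the
  interval length; the polynomial-times-exponential antiderivative for
  the division kind switches to its polynomial limit when |c·Δ| < 1e-10.
* Monte-Carlo oracle: inverse-CDF sampling on a 4097-point grid (bias
  orders of magnitude below the Monte-Carlo standard error at 10⁶
  draws).

## Problem sizes in the shipped test suite

The end-to-end recovery and selection experiments run at reduced sizes
chosen once: 200 patients for the exponential-family models, 150 for
Gompertz and Gyllenberg–Webb, 250 for the treatment model; 8–15
optimisation starts; tempered chains of 8000 sweeps (5000 for the
costlier Gyllenberg–Webb likelihood) over 3 temperatures with the first
half discarded.  The chain lengths were set from mixing diagnostics:
2500-sweep chains gave effective sample sizes near 50 and visibly
underestimated 95% interval widths, while at these lengths the effective
sample size per parameter exceeds ~100 and the quantiles are stable.  The likelihood-agreement check uses the
full 500-patient cohorts and 100 random parameter vectors, and the
treatment-effect experiment in `scripts/acceptance.py` runs at full
scale (500 patients, 100 starts).

## What the synthetic data do and do not show

The generator reproduces the features the likelihood is built for —
scheduled noisy size measurements, exact counts, exactly-observed
deaths, censoring, and registry-style missingness that is independent of
the process.  It does not emulate informative visit schedules, real
radiological error structure, metastasis growth or per-metastasis
detection, or inter-patient parameter heterogeneity (random effects).
Passing tests therefore demonstrate correctness of the simulator,
likelihood and inference machinery under the model's own assumptions,
not the adequacy of those assumptions for any particular clinical
dataset.

## Known limitations

* The closed-form likelihood path requires (piecewise-)exponential
  growth; other growth laws use the numeric path (still fast, but
  gradient-free optimisation territory — the implementation uses
  finite-difference L-BFGS-B, which behaves well because the quadrature
  is smooth and deterministic).
* Covariates act on the growth rate only; covariate-dependent seeding or
  death rates are not implemented (no concrete functional form to
  target).
* The death hazard must be linear in N for the rank-1 reduction; the
  nested cubature route would remain correct for nonlinear-in-N hazards
  but is not wired up as a standalone likelihood.
* d_metas is weakly identified in small cohorts (it sits behind two
  layers of stochasticity); expect wide, right-skewed posteriors.
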