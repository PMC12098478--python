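"""Parameter inference: multistart MLE, parallel-tempering MCMC, AIC.

All parameters are positive rates or volumes, so optimisation and
sampling work on natural-log scale inside box bounds.  Maximum-likelihood
estimation launches many L-BFGS-B local searches from log-uniform start
points (the likelihood routes are smooth in the parameters, so
quasi-Newton search with finite-difference gradients converges reliably);
a bounded dual-annealing fallback is available for rugged objectives.

Posterior uncertainty uses an adaptive parallel-tempering
Metropolis-Hastings sampler: a geometric temperature ladder, per-
temperature random-walk proposals whose scale and covariance adapt
during the run, and state swaps between adjacent temperatures.  The
first half of every chain is discarded as burn-in and central credibility
intervals are read off the cold chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import dual_annealing, minimize

from .likelihood import CohortLikelihood
from .models import ModelSpec
from .simulate import Cohort

__all__ = [
    "FitResult",
    "PosteriorSamples",
    "fit_mle",
    "sample_posterior",
    "credibility_intervals",
    "aic",
    "select_model",
]


@dataclass
class FitResult:
    """Outcome of a multistart maximum-likelihood fit."""

    model_name: str
    param_names: tuple
    log_theta_mle: np.ndarray
    neg_loglik: float
    n_params: int
    start_values: np.ndarray  # final objective value per start
    start_points: np.ndarray  # log-scale start points
    converged: np.ndarray  # per-start success flags
    best_start: int
    cohort_tag: Optional[dict] = None

    @property
    def theta_mle(self) -> dict:
        return dict(zip(self.param_names, np.exp(self.log_theta_mle)))

    @property
    def log_theta_dict(self) -> dict:
        return dict(zip(self.param_names, self.log_theta_mle))

    @property
    def loglik(self) -> float:
        return -self.neg_loglik


@dataclass
class PosteriorSamples:
    """Post burn-in samples of the cold chain(s), log scale."""

    param_names: tuple
    chains: np.ndarray  # (n_chains, n_kept, n_params)
    temperatures: np.ndarray
    acceptance: np.ndarray  # per-temperature acceptance rates, averaged
    swap_acceptance: float

    @property
    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])


def _cohort_tag(cohort: Cohort) -> dict:
    prov = dict(cohort.provenance)
    return {
        "n_patients": len(cohort),
        "model": prov.get("model"),
        "seed": prov.get("seed"),
        "masking": prov.get("masking"),
    }


def fit_mle(
    model: ModelSpec,
    cohort: Cohort,
    bounds: Optional[dict] = None,
    n_starts: int = 100,
    seed: int = 0,
    method: str = "auto",
    optimizer: str = "lbfgs",
    likelihood: Optional[CohortLikelihood] = None,
) -> FitResult:
    """Multistart maximum-likelihood estimate on log-scale parameters.

    Start points are drawn log-uniformly inside the (log-scale) box
    ``bounds`` (defaults to the model's shipped bounds).  Every start is
    polished by L-BFGS-B (or bounded dual annealing when
    ``optimizer='anneal'``); the best optimum wins, ties broken by start
    index.
    """
    if n_starts < 1:
        raise ValueError("need n_starts >= 1")
    bounds = bounds or model.log_bounds
    lo = np.array([bounds[n][0] for n in model.free_names], dtype=float)
    hi = np.array([bounds[n][1] for n in model.free_names], dtype=float)
    if not np.all(np.isfinite(lo) & np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite with low < high")
    cl = likelihood or CohortLikelihood(model, cohort)

    def objective(log_theta):
        return cl.negloglik(np.exp(log_theta), method=method)

    rng = np.random.default_rng(seed)
    starts = lo + (hi - lo) * rng.random((n_starts, lo.size))
    box = list(zip(lo, hi))
    results = []
    for x0 in starts:
        if optimizer == "lbfgs":
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=box,
                options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
            )
            # restart polish: re-running from the incumbent clears a stale
            # quasi-Newton Hessian and rescues prematurely-stopped starts
            for _ in range(3):
                again = minimize(
                    objective,
                    res.x,
                    method="L-BFGS-B",
                    bounds=box,
                    options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
                )
                if not np.isfinite(again.fun) or again.fun > res.fun - 1e-9:
                    res = again if again.fun <= res.fun else res
                    break
                res = again
            # gradient-free refinement: finite-difference gradients stall
            # on flat ridges of the numeric-likelihood models; a simplex
            # polish from the incumbent converges the last distance
            if np.isfinite(res.fun):
                nm = minimize(
                    objective,
                    res.x,
                    method="Nelder-Mead",
                    bounds=box,
                    options={
                        "xatol": 1e-7,
                        "fatol": 1e-10,
                        "maxiter": 2000,
                        "initial_simplex": res.x
                        + 1e-3 * np.vstack([np.zeros(lo.size), np.eye(lo.size)]),
                    },
                )
                if np.isfinite(nm.fun) and nm.fun < res.fun:
                    nm.success = nm.success or res.success
                    res = nm
        elif optimizer == "anneal":
            res = dual_annealing(
                objective,
                bounds=box,
                x0=x0,
                seed=int(rng.integers(2**31 - 1)),
                maxiter=200,
            )
        else:
            raise ValueError(f"unknown optimizer {optimizer!r}")
        results.append(res)
    values = np.array([r.fun for r in results], dtype=float)
    success = np.array([bool(r.success) and np.isfinite(r.fun) for r in results])
    if not np.any(np.isfinite(values)):
        raise RuntimeError(
            "all optimisation starts failed; check bounds and data "
            f"(messages: {set(getattr(r, 'message', '') for r in results)})"
        )
    best = int(np.nanargmin(np.where(np.isfinite(values), values, np.inf)))
    return FitResult(
        model_name=model.name,
        param_names=tuple(model.free_names),
        log_theta_mle=np.asarray(results[best].x, dtype=float),
        neg_loglik=float(values[best]),
        n_params=len(model.free_names),
        start_values=values,
        start_points=starts,
        converged=success,
        best_start=best,
        cohort_tag=_cohort_tag(cohort),
    )


def sample_posterior(
    model: ModelSpec,
    cohort: Cohort,
    theta_init,
    seed: int = 0,
    n_iter: int = 50_000,
    n_temps: int = 4,
    n_chains: int = 3,
    max_temp: float = 25.0,
    bounds: Optional[dict] = None,
    method: str = "auto",
    likelihood: Optional[CohortLikelihood] = None,
) -> PosteriorSamples:
    """Adaptive parallel-tempering MCMC around the posterior of log-theta.

    The prior is uniform on the log-scale box.  ``theta_init`` is a
    log-scale vector (e.g. ``FitResult.log_theta_mle``); the likelihood
    must be finite there.  Each of ``n_chains`` independent replicates
    runs ``n_iter`` sweeps over a geometric temperature ladder; the first
    half is discarded.
    """
    bounds = bounds or model.log_bounds
    lo = np.array([bounds[n][0] for n in model.free_names], dtype=float)
    hi = np.array([bounds[n][1] for n in model.free_names], dtype=float)
    x0 = np.asarray(theta_init, dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("theta_init lies outside the log-scale bounds")
    d = x0.size
    cl = likelihood or CohortLikelihood(model, cohort)

    def loglik(x):
        return -cl.negloglik(np.exp(x), method=method)

    ll0 = loglik(x0)
    if not np.isfinite(ll0):
        raise ValueError("likelihood is not finite at theta_init")
    betas = (1.0 / max_temp) ** (np.arange(n_temps) / max(n_temps - 1, 1))
    keep = n_iter - n_iter // 2
    chains = np.empty((n_chains, keep, d))
    acc_all = np.zeros(n_temps)
    swap_acc = 0
    swap_tot = 0
    root = np.random.SeedSequence(seed)
    for c, ss in enumerate(root.spawn(n_chains)):
        rng = np.random.default_rng(ss)
        x = np.tile(x0, (n_temps, 1)) + 0.01 * (hi - lo) * rng.standard_normal((n_temps, d))
        x = np.clip(x, lo, hi)
        ll = np.array([loglik(xi) for xi in x])
        scale = np.full(n_temps, 0.2)
        mean = x.copy()
        cov = np.tile(np.diag(((hi - lo) / 20.0) ** 2), (n_temps, 1, 1))
        chol = np.linalg.cholesky(cov)
        accepted = np.zeros(n_temps)
        for it in range(n_iter):
            for k in range(n_temps):
                prop = x[k] + scale[k] * chol[k] @ rng.standard_normal(d)
                if np.any(prop < lo) or np.any(prop > hi):
                    lp = -math.inf
                else:
                    lp = loglik(prop)
                if math.log(rng.random() + 1e-300) < betas[k] * (lp - ll[k]):
                    x[k] = prop
                    ll[k] = lp
                    accepted[k] += 1
                # Robbins-Monro step-size adaptation towards 23% acceptance
                gamma = 1.0 / (1.0 + it) ** 0.6
                alpha = min(1.0, math.exp(min(betas[k] * (lp - ll[k]), 0.0))) if np.isfinite(lp) else 0.0
                scale[k] *= math.exp(gamma * (alpha - 0.234))
                # running covariance adaptation (Haario-style)
                w = max(gamma, 1.0 / (it + 2))
                mean[k] = (1 - w) * mean[k] + w * x[k]
                dev = (x[k] - mean[k])[:, None]
                cov[k] = (1 - w) * cov[k] + w * (dev @ dev.T + 1e-10 * np.eye(d))
                if it % 50 == 0:
                    try:
                        chol[k] = np.linalg.cholesky(cov[k])
                    except np.linalg.LinAlgError:
                        pass
            # one swap attempt between a random adjacent pair per sweep
            if n_temps > 1:
                k = int(rng.integers(n_temps - 1))
                log_r = (betas[k] - betas[k + 1]) * (ll[k + 1] - ll[k])
                swap_tot += 1
                if math.log(rng.random() + 1e-300) < log_r:
                    x[[k, k + 1]] = x[[k + 1, k]]
                    ll[[k, k + 1]] = ll[[k + 1, k]]
                    swap_acc += 1
            if it >= n_iter - keep:
                chains[c, it - (n_iter - keep)] = x[0]
        acc_all += accepted / n_iter
    return PosteriorSamples(
        param_names=tuple(model.free_names),
        chains=chains,
        temperatures=1.0 / betas,
        acceptance=acc_all / n_chains,
        swap_acceptance=swap_acc / max(swap_tot, 1),
    )


def credibility_intervals(
    samples: PosteriorSamples, levels: Sequence[float] = (0.8, 0.9, 0.95)
) -> dict:
    """Central posterior intervals per parameter and level (log scale).

    Returns {param: {level: (low, high)}}; intervals are nested by
    construction.
    """
    flat = samples.flat
    if flat.size == 0:
        raise ValueError("no post burn-in samples")
    out = {}
    for j, name in enumerate(samples.param_names):
        out[name] = {}
        for g in levels:
            lo_q, hi_q = (1.0 - g) / 2.0, (1.0 + g) / 2.0
            out[name][g] = (
                float(np.quantile(flat[:, j], lo_q)),
                float(np.quantile(flat[:, j], hi_q)),
            )
    return out


def aic(fit: FitResult) -> float:
    """Akaike information criterion 2p - 2*loglik (lower is better)."""
    return 2.0 * fit.n_params - 2.0 * fit.loglik


def select_model(fits: Sequence[FitResult]) -> dict:
    """Delta-AIC table across candidate fits of the same cohort.

    Returns {'aic': {name: AIC}, 'delta_aic': {name: AIC - min},
    'best': name}.  Fits on differing cohorts are rejected.
    """
    if not fits:
        raise ValueError("need at least one fit")
    tags = [f.cohort_tag for f in fits]
    if any(t != tags[0] for t in tags[1:]):
        raise ValueError("model selection requires fits on the same cohort")
    aics = {f.model_name: aic(f) for f in fits}
    best = min(aics, key=aics.get)
    return {
        "aic": aics,
        "delta_aic": {k: v - aics[best] for k, v in aics.items()},
        "best": best,
    }
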