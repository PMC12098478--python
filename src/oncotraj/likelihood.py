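"""Patient and cohort likelihoods for the combined model.

The likelihood of one patient factorises over inter-visit intervals into

* a Gaussian (or log-normal) term for each noisy tumour-size measurement,
* a Poisson-increment term for each observed metastasis-count increment,
  with mean Lambda_N over the interval,
* a marginal survival probability for each interval survived, and the
  death density (hazard at the death time x survival probability) for the
  final interval of patients who die.

The survival probability conditional on m new metastases in [t_a, t_b) is
an m-dimensional integral over the ordered jump times.  Because the death
intensity is linear in the metastasis count with a coefficient that does
not depend on the jump positions, that integral collapses exactly to a
one-dimensional integral raised to the m-th power:

    P(survive | m jumps) = exp(-d_size*int sqrt(S) - d_metas*n_prev*dt) * J^m,
    J = (1/Lambda_N) int lambda_N(u) exp(-d_metas (t_b - u)) du.

This *rank-1 reduction* is the analytic fast path (fully closed form for
exponential growth).  Two independent evaluations guard it: a direct
nested Clenshaw-Curtis cubature of the simplex integral, and a
Monte-Carlo average over conditional jump times.

Missing data are marginalised exactly: a missing size measurement drops
its observation term; a missing count at an interior visit survived
through is skipped via the Chapman-Kolmogorov equation (intervals merge);
a missing count on a death row is summed out up to a cut-off M_max (the
largest count seen in the data); a missing count on a censored final row
uses the closed-form Poisson marginal exp(-(Lambda - J*Lambda)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .growth import (
    ExponentialGrowth,
    PiecewiseExponentialGrowth,
)
from .intensities import (
    _expm1_ratio,
    cumulative_metastasis_intensity,
    death_intensity,
    metastasis_intensity,
    sqrt_volume_integral,
)
from .models import ModelSpec
from .quadrature import (
    ChebCumulative,
    cc_quad,
    cheb_coeffs,
    cheb_eval,
    cheb_integral,
    cheb_nodes,
)
from .simulate import Cohort, PatientRecord

__all__ = [
    "LikelihoodValue",
    "size_observation_loglik",
    "metastasis_increment_loglik",
    "survival_interval_prob",
    "death_interval_density",
    "mc_survival_oracle",
    "patient_loglik",
    "cohort_negloglik",
    "CohortLikelihood",
]

NEG_INF = -math.inf


# ---------------------------------------------------------------------------
# elementary terms
# ---------------------------------------------------------------------------
def size_observation_loglik(
    S_model, S_obs, sigma_S: float, noise_kind: str = "gaussian_proportional"
):
    """Log-density of a noisy size measurement given the model volume.

    Gaussian noise has mean S_model and standard deviation sigma_S*S_model;
    the log-normal alternative has log-scale sd sigma_S and median S_model.
    Missing observations (NaN) contribute 0.
    """
    S_model = np.asarray(S_model, dtype=float)
    S_obs = np.asarray(S_obs, dtype=float)
    if np.any(S_model <= 0):
        raise ValueError("model volume must be positive")
    if sigma_S <= 0:
        raise ValueError("sigma_S must be positive")
    missing = np.isnan(S_obs)
    if noise_kind == "gaussian_proportional":
        sd = sigma_S * S_model
        lp = -0.5 * np.log(2.0 * math.pi * sd**2) - (S_obs - S_model) ** 2 / (2.0 * sd**2)
    elif noise_kind == "lognormal":
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(
                S_obs > 0,
                -np.log(S_obs * sigma_S * math.sqrt(2.0 * math.pi))
                - (np.log(S_obs) - np.log(S_model)) ** 2 / (2.0 * sigma_S**2),
                NEG_INF,
            )
    else:
        raise ValueError(f"unknown noise kind {noise_kind!r}")
    return np.where(missing, 0.0, lp)


def metastasis_increment_loglik(Lambda, dn):
    """Poisson log-probability of a count increment: dn*ln(L) - L - ln(dn!).

    The degenerate case Lambda=0, dn=0 gives 0; Lambda=0 with dn>0 gives
    the -inf sentinel (impossible data).
    """
    Lambda = np.asarray(Lambda, dtype=float)
    dn = np.asarray(dn)
    if np.any(Lambda < 0):
        raise ValueError("Lambda must be non-negative")
    if np.any(dn < 0) or not np.all(np.equal(np.mod(dn, 1), 0)):
        raise ValueError(f"count increments must be non-negative integers, got {dn}")
    dn = dn.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = dn * np.log(Lambda) - Lambda - gammaln(dn + 1.0)
        lp = np.where((Lambda == 0) & (dn == 0), 0.0, lp)
        lp = np.where((Lambda == 0) & (dn > 0), NEG_INF, lp)
    return lp


# ---------------------------------------------------------------------------
# the weighted seeding integral  int lambda_N(u) exp(-d (t_b - u)) du
# ---------------------------------------------------------------------------
def _weighted_integral_exponential_piece(met, a, b, s_a, beta, t_end, d):
    """Closed form of int_a^b lambda_N(u) e^{-d (t_end - u)} du for a
    constant-rate exponential piece (volume kind)."""
    dt = b - a
    damp = math.exp(-d * (t_end - a))
    term_basal = met.m_basal * dt * float(_expm1_ratio(d * dt))
    term_size = (
        met.m_size * math.sqrt(s_a) * dt * float(_expm1_ratio((beta / 2.0 + d) * dt))
    )
    return damp * (term_basal + term_size)


def _poly_exp_integral(a_lo, a_hi, k: int, c):
    """int_{a_lo}^{a_hi} w^k e^{c (w - a_lo)} dw for integer k >= 0, vectorised."""
    a_lo = np.asarray(a_lo, dtype=float)
    a_hi = np.asarray(a_hi, dtype=float)
    c = np.asarray(c, dtype=float)
    small = np.abs(c) * np.maximum(np.abs(a_hi - a_lo), 1.0) < 1e-10
    c_safe = np.where(small, 1.0, c)
    # antiderivative F(w) = e^{cw} sum_j (-1)^j k!/(k-j)! w^{k-j} / c^{j+1}
    def F(w):
        total = np.zeros(np.broadcast(w, c_safe).shape)
        coef = 1.0
        for j in range(k + 1):
            total = total + (-1.0) ** j * coef * w ** (k - j) / c_safe ** (j + 1)
            coef *= k - j
        return total

    exact = np.exp(-c_safe * a_lo) * (
        np.exp(c_safe * a_hi) * F(a_hi) - np.exp(c_safe * a_lo) * F(a_lo)
    )
    limit = (a_hi ** (k + 1) - a_lo ** (k + 1)) / (k + 1.0)
    return np.where(small, limit, exact)


def _weighted_metastasis_integral(met, growth, t_a, t_b, t_end, d):
    """int_{t_a}^{t_b} lambda_N(u) exp(-d (t_end - u)) du.

    Closed form for (piecewise-)exponential growth; adaptive quadrature
    otherwise.
    """
    if d == 0.0:
        return cumulative_metastasis_intensity(met, growth, t_a, t_b)
    if isinstance(growth, ExponentialGrowth):
        pieces = [(t_a, t_b, float(growth.volume(t_a)), growth.beta)]
    elif isinstance(growth, PiecewiseExponentialGrowth):
        pieces = growth.pieces_between(t_a, t_b)
    else:
        pieces = None
    if pieces is not None and met.kind == "volume":
        return sum(
            _weighted_integral_exponential_piece(met, a, b, s_a, beta, t_end, d)
            for a, b, s_a, beta in pieces
        )
    if (
        pieces is not None
        and met.kind == "cell_division"
        and float(met.k_exp).is_integer()
    ):
        k = int(met.k_exp)
        total = 0.0
        ln2 = math.log(2.0)
        for a, b, s_a, beta in pieces:
            if beta == 0.0:
                continue  # A constant on the piece, lambda_N = 0
            a_lo = (math.log(s_a) - math.log(met.S_cell)) / ln2
            a_hi = a_lo + beta * (b - a) / ln2
            c = d * ln2 / beta
            total += (
                met.m_division
                * ln2
                * math.exp(-d * (t_end - a))
                * float(_poly_exp_integral(a_lo, a_hi, k, c))
            )
        return total
    return cc_quad(
        lambda u: metastasis_intensity(met, growth, u) * np.exp(-d * (t_end - u)),
        t_a,
        t_b,
        rel_tol=1e-10,
        abs_tol=1e-14,
    )


# ---------------------------------------------------------------------------
# marginal survival probability (Theorem-style interval terms)
# ---------------------------------------------------------------------------
def _interval_components(model, theta, t_prev, t_next, covariates):
    params = model.params(theta)
    growth = model.build_growth(params, covariates)
    met = model.build_metastasis(params)
    death = model.build_death(params)
    return params, growth, met, death


def _cc_weights(n: int) -> np.ndarray:
    """Clenshaw-Curtis weights on [-1, 1] for the Lobatto points of degree n."""
    return cheb_integral(cheb_coeffs(np.eye(n + 1)))


class _ChebPack:
    """Chebyshev interpolant + cumulative integral of a function on an
    interval, built from values at Lobatto points (batched)."""

    def __init__(self, fvals, a, b):
        self.coeffs = cheb_coeffs(np.atleast_2d(np.asarray(fvals, dtype=float)))
        self.cumulative = ChebCumulative(fvals, a, b)
        self.a = self.cumulative.a
        self.b = self.cumulative.b

    def value(self, t):
        extra = np.asarray(t).ndim - self.a.ndim
        mid = self.cumulative.mid.reshape(self.cumulative.mid.shape + (1,) * extra)
        half = self.cumulative.half.reshape(self.cumulative.half.shape + (1,) * extra)
        co = self.coeffs.reshape(
            self.coeffs.shape[:-1] + (1,) * extra + self.coeffs.shape[-1:]
        )
        x = (np.asarray(t, dtype=float) - mid) / np.where(half > 0, half, 1.0)
        return cheb_eval(co, x)

    def cum(self, t):
        return self.cumulative.cum(t)

    @property
    def total(self):
        return self.cumulative.total


def _simplex_nodes(m: int, n_1d: int):
    """Tensor Clenshaw-Curtis rule on the unit cube [0,1]^m."""
    x = (cheb_nodes(n_1d)[::-1] + 1.0) / 2.0
    w = _cc_weights(n_1d)[::-1] / 2.0
    grids = np.meshgrid(*([x] * m), indexing="ij")
    v = np.stack([g.ravel() for g in grids], axis=-1)  # (P, m)
    wgrids = np.meshgrid(*([w] * m), indexing="ij")
    wgrid = np.prod(np.stack([g.ravel() for g in wgrids], axis=-1), axis=-1)
    return v, wgrid


def _cubature_survival_batch(
    lam_pack: _ChebPack,
    g_pack: _ChebPack,
    t_a,
    t_b,
    n_prev,
    m: int,
    d_size: float,
    d_metas: float,
    n_1d: int,
):
    """Direct nested cubature of the ordered-jump-time simplex integral,
    vectorised over a batch of intervals sharing the same m.

    Maps the ordered simplex to the unit cube (u_i = u_{i-1} +
    (t_b - u_{i-1}) v_i) and applies a tensor Clenshaw-Curtis rule; the
    integrated hazard between consecutive jump times comes from the
    Chebyshev cumulative of sqrt(S).
    """
    t_a = np.atleast_1d(np.asarray(t_a, dtype=float))
    t_b = np.atleast_1d(np.asarray(t_b, dtype=float))
    n_prev = np.atleast_1d(np.asarray(n_prev, dtype=float))
    B = t_a.shape[0]
    if m == 0:
        haz = d_size * g_pack.total + d_metas * n_prev * (t_b - t_a)
        return np.exp(-haz)
    v, w = _simplex_nodes(m, n_1d)  # (P, m), (P,)
    P = v.shape[0]
    u = np.empty((B, P, m + 2))
    u[:, :, 0] = t_a[:, None]
    jac = np.ones((B, P))
    for i in range(m):
        rem = t_b[:, None] - u[:, :, i]
        u[:, :, i + 1] = u[:, :, i] + rem * v[None, :, i]
        jac = jac * rem
    u[:, :, m + 1] = t_b[:, None]
    lam_vals = lam_pack.value(u[:, :, 1 : m + 1])  # (B, P, m)
    g_vals = g_pack.cum(u)  # (B, P, m+2)
    seg_dt = np.diff(u, axis=-1)  # (B, P, m+1)
    counts = n_prev[:, None, None] + np.arange(m + 1)[None, None, :]
    haz = d_size * (g_vals[..., 1:] - g_vals[..., :-1]) + d_metas * counts * seg_dt
    integrand = np.prod(np.maximum(lam_vals, 0.0), axis=-1) * np.exp(
        -np.sum(haz, axis=-1)
    )
    nested = np.einsum("bp,p->b", integrand * jac, w)
    lam_total = np.maximum(lam_pack.total, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = math.factorial(m) * nested / lam_total**m
    return out


def _build_packs(met, growth, t_a: float, t_b: float, degree: int = 32):
    nodes = 0.5 * (t_a + t_b) + 0.5 * (t_b - t_a) * cheb_nodes(degree)
    lam = metastasis_intensity(met, growth, nodes)
    rootS = np.sqrt(np.asarray(growth.volume(nodes), dtype=float))
    a = np.array([t_a])
    b = np.array([t_b])
    return _ChebPack(lam, a, b), _ChebPack(rootS, a, b)


def survival_interval_prob(
    model: ModelSpec,
    theta,
    t_prev: float,
    t_next: float,
    n_prev: int,
    m: int,
    covariates: Optional[dict] = None,
    method: str = "auto",
    rel_tol: float = 1e-8,
) -> float:
    """Probability of surviving [t_prev, t_next) given m new metastases.

    ``method='auto'`` uses the rank-1 reduction with closed-form integrals
    where available and adaptive quadrature otherwise; ``'cubature'``
    forces the direct nested simplex integral (the independent numeric
    route).  The result lies in (0, 1].
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if not t_prev < t_next:
        raise ValueError("need t_prev < t_next")
    params, growth, met, death = _interval_components(model, theta, t_prev, t_next, covariates)
    dt = t_next - t_prev
    if method in ("auto", "reduction", "closed_form"):
        i_s = death.d_size * sqrt_volume_integral(growth, t_prev, t_next)
        base = math.exp(-i_s - death.d_metas * n_prev * dt)
        if m == 0:
            return base
        lam_total = cumulative_metastasis_intensity(met, growth, t_prev, t_next)
        if lam_total <= 0:
            raise ValueError("m > 0 but the metastasis intensity integrates to zero")
        jlam = _weighted_metastasis_integral(
            met, growth, t_prev, t_next, t_next, death.d_metas
        )
        return base * (jlam / lam_total) ** m
    if method != "cubature":
        raise ValueError(f"unknown method {method!r}")
    lam_pack, g_pack = _build_packs(met, growth, t_prev, t_next)
    caps = {1: 64, 2: 64, 3: 32, 4: 24, 5: 16}
    n_cap = caps.get(m, 12)
    schedule = [n for n in (8, 12, 16, 24, 32, 48, 64) if n <= n_cap]
    prev = None
    change = math.inf
    for n_1d in schedule:
        est = float(
            _cubature_survival_batch(
                lam_pack, g_pack, [t_prev], [t_next], [n_prev], m,
                death.d_size, death.d_metas, n_1d,
            )[0]
        )
        if prev is not None:
            change = abs(est - prev)
            if change <= max(1e-9, rel_tol * abs(est)):
                return est
        prev = est
    import warnings

    warnings.warn(
        f"survival cubature stopped at n={schedule[-1]} per dimension "
        f"(last change {change:.3g})"
    )
    return est


def death_interval_density(
    model: ModelSpec,
    theta,
    t_prev: float,
    t_death: float,
    n_prev: int,
    m: int,
    covariates: Optional[dict] = None,
    method: str = "auto",
) -> float:
    """Density of death at t_death given m new metastases since t_prev:
    lambda_D(t_death, S(t_death), n_prev + m) times the survival
    probability of the interval."""
    params, growth, met, death = _interval_components(model, theta, t_prev, t_death, covariates)
    lam_d = float(death_intensity(death, growth, t_death, n_prev + m))
    return lam_d * survival_interval_prob(
        model, theta, t_prev, t_death, n_prev, m, covariates, method
    )


def mc_survival_oracle(
    model: ModelSpec,
    theta,
    t_prev: float,
    t_next: float,
    n_prev: int,
    m: int,
    n_samples: int = 100_000,
    seed: int = 0,
    covariates: Optional[dict] = None,
):
    """Monte-Carlo estimate of the conditional survival probability.

    Draws the m jump times i.i.d. with density lambda_N/Lambda_N (inverse
    CDF on a dense grid), sorts them, and averages exp(-integrated death
    hazard) along the resulting piecewise-constant count path.  Unbiased;
    returns (estimate, standard_error).
    """
    if n_samples < 1:
        raise ValueError("need n_samples >= 1")
    params, growth, met, death = _interval_components(model, theta, t_prev, t_next, covariates)
    lam_pack, g_pack = _build_packs(met, growth, t_prev, t_next)
    dt = t_next - t_prev
    base_haz = death.d_size * float(g_pack.total[0]) + death.d_metas * n_prev * dt
    if m == 0:
        return math.exp(-base_haz), 0.0
    rng = np.random.default_rng(seed)
    grid = np.linspace(t_prev, t_next, 4097)
    cum = lam_pack.cum(grid[None, :])[0]
    cum = np.maximum.accumulate(np.maximum(cum, 0.0))
    total = cum[-1]
    if total <= 0:
        raise ValueError("metastasis intensity integrates to zero on the interval")
    targets = rng.random((n_samples, m)) * total
    u = np.sort(np.interp(targets, cum, grid), axis=1)
    pts = np.concatenate(
        [np.full((n_samples, 1), t_prev), u, np.full((n_samples, 1), t_next)], axis=1
    )
    # integrated sqrt-volume between jump times via a dense-grid cumulative
    # (linear interpolation on 4097 points is far below the MC error)
    g_grid = g_pack.cum(grid[None, :])[0]
    g_vals = np.interp(pts, grid, g_grid)
    seg_dt = np.diff(pts, axis=1)
    counts = n_prev + np.arange(m + 1)[None, :]
    haz = np.sum(
        death.d_size * np.diff(g_vals, axis=1) + death.d_metas * counts * seg_dt,
        axis=1,
    )
    vals = np.exp(-haz)
    est = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(n_samples))
    return est, se


# ---------------------------------------------------------------------------
# compiled cohort likelihood
# ---------------------------------------------------------------------------
@dataclass
class LikelihoodValue:
    """A log-likelihood with its per-term and per-patient breakdown."""

    loglik: float
    observation: float
    metastasis: float
    survival_death: float
    per_patient: np.ndarray = field(default_factory=lambda: np.zeros(0))


class _CompiledCohort:
    """Static arrays extracted from a cohort once, reused for every
    likelihood evaluation during optimisation or sampling."""

    MISSING = -1

    def __init__(self, model: ModelSpec, cohort: Cohort, M_max: Optional[int] = None):
        self.model = model
        self.n_patients = len(cohort)
        n0 = float(model.params().get("N0", 0))
        it_a, it_b, i_n, i_m, i_death, i_pat = [], [], [], [], [], []
        obs_t, obs_v, obs_pat = [], [], []
        self.covariates = []
        max_count = 0
        for p, rec in enumerate(cohort):
            rec.validate()
            self.covariates.append(rec.covariates or {})
            n_obs_mask = ~np.isnan(rec.n_metastases)
            if n_obs_mask.any():
                max_count = max(max_count, int(np.nanmax(rec.n_metastases)))
            for t, v in zip(rec.times, rec.size_obs):
                if np.isfinite(v):
                    obs_t.append(float(t))
                    obs_v.append(float(v))
                    obs_pat.append(p)
            if rec.times.size == 0:
                continue
            # anchors: detection (t=0, N=N0) + observed-count rows + final row
            anchors = [(0.0, n0, False)]
            last = rec.times.size - 1
            for j, t in enumerate(rec.times):
                n_j = rec.n_metastases[j]
                is_final = j == last
                is_death = bool(rec.death[j] == 1)
                if t <= 0.0:
                    if np.isfinite(n_j):
                        anchors[0] = (0.0, float(n_j), is_death)
                    continue
                if np.isfinite(n_j):
                    anchors.append((float(t), float(n_j), is_death))
                elif is_final:
                    anchors.append((float(t), np.nan, is_death))
                # interior rows with missing counts are skipped
                # (Chapman-Kolmogorov merge of the adjacent intervals)
            for (ta, na, _), (tb, nb, db) in zip(anchors, anchors[1:]):
                it_a.append(ta)
                it_b.append(tb)
                i_n.append(int(na))
                i_m.append(self.MISSING if np.isnan(nb) else int(nb - na))
                i_death.append(db)
                i_pat.append(p)
        self.it_a = np.asarray(it_a, dtype=float)
        self.it_b = np.asarray(it_b, dtype=float)
        self.i_n = np.asarray(i_n, dtype=float)
        self.i_m = np.asarray(i_m, dtype=int)
        self.i_death = np.asarray(i_death, dtype=bool)
        self.i_pat = np.asarray(i_pat, dtype=int)
        self.obs_t = np.asarray(obs_t, dtype=float)
        self.obs_v = np.asarray(obs_v, dtype=float)
        self.obs_pat = np.asarray(obs_pat, dtype=int)
        self.M_max = int(M_max) if M_max is not None else max(max_count, 5)
        self.n_intervals = self.it_a.size
        self._build_pieces()
        self._node_degree = 32
        nodes = cheb_nodes(self._node_degree)
        self.node_t = (
            0.5 * (self.it_a + self.it_b)[:, None]
            + 0.5 * (self.it_b - self.it_a)[:, None] * nodes[None, :]
        )

    # -- covariate pieces for the exponential-family closed path ------------
    def _build_pieces(self):
        """Split each interval at covariate break points and set up the
        per-patient cumulative-rate bookkeeping for S(t)."""
        pc_a, pc_b, pc_itv, pc_treat, pc_obese, pc_pat = [], [], [], [], [], []
        for i in range(self.n_intervals):
            p = self.i_pat[i]
            cov = self.covariates[p]
            t_rx = cov.get("treatment_start", None)
            obese = float(cov.get("obese", 0.0))
            ta, tb = self.it_a[i], self.it_b[i]
            cuts = [ta, tb]
            if t_rx is not None and np.isfinite(t_rx) and ta < t_rx < tb:
                cuts = [ta, float(t_rx), tb]
            for a, b in zip(cuts, cuts[1:]):
                treated = (
                    1.0
                    if (t_rx is not None and np.isfinite(t_rx) and a >= t_rx - 1e-12)
                    else 0.0
                )
                pc_a.append(a)
                pc_b.append(b)
                pc_itv.append(i)
                pc_treat.append(treated)
                pc_obese.append(obese)
                pc_pat.append(p)
        self.pc_a = np.asarray(pc_a, dtype=float)
        self.pc_b = np.asarray(pc_b, dtype=float)
        self.pc_itv = np.asarray(pc_itv, dtype=int)
        self.pc_treat = np.asarray(pc_treat, dtype=float)
        self.pc_obese = np.asarray(pc_obese, dtype=float)
        self.pc_pat = np.asarray(pc_pat, dtype=int)
        # pieces of one patient are contiguous and tile [0, t_last]
        first = np.zeros(self.n_patients, dtype=int)
        seen = set()
        for idx, p in enumerate(self.pc_pat):
            if p not in seen:
                first[p] = idx
                seen.add(p)
        self.pc_first = first
        # index of the last piece belonging to each interval
        last_of_itv = np.zeros(self.n_intervals, dtype=int)
        for idx, i in enumerate(self.pc_itv):
            last_of_itv[i] = idx
        self.pc_last = last_of_itv
        # observation rows: piece owning each row time, for S(t) lookup
        self.obs_piece = np.zeros(self.obs_t.size, dtype=int)
        for k in range(self.obs_t.size):
            p, t = self.obs_pat[k], self.obs_t[k]
            mask = (self.pc_pat == p) & (self.pc_a <= t + 1e-12) & (t <= self.pc_b + 1e-12)
            idx = np.nonzero(mask)[0]
            self.obs_piece[k] = idx[0] if idx.size else self.pc_first[p]
        # covariate flags at observation times (for the rate at that time)
        self.obs_treat = self.pc_treat[self.obs_piece]
        self.obs_obese = self.pc_obese[self.obs_piece]


class CohortLikelihood:
    """Vectorised negative log-likelihood of a cohort under a model.

    Compile once, evaluate many times (optimisation, MCMC).  Three
    evaluation routes share the compiled arrays:

    ``closed_form``
        exact closed-form interval integrals; available for (piecewise-)
        exponential growth with either metastasis kind,
    ``quadrature``
        the same rank-1 reduction with the interval integrals computed by
        fixed high-degree Clenshaw-Curtis rules (any growth law),
    ``cubature``
        direct nested simplex cubature of the marginal survival integrals
        -- the independent numeric route used for validation.
    """

    _CUBATURE_NODES = {1: 32, 2: 16, 3: 12, 4: 10, 5: 8, 6: 8}

    def __init__(self, model: ModelSpec, cohort: Cohort, M_max: Optional[int] = None):
        self.model = model
        self.c = _CompiledCohort(model, cohort, M_max=M_max)
        self.closed_form_available = model.growth_law in (
            "exponential",
            "covariate_exponential",
        ) and (
            model.metastasis_kind == "volume"
            or float(model.params().get("k_exp", 1.0)).is_integer()
        )

    # -- growth evaluation helpers ------------------------------------------
    def _piece_arrays(self, params):
        """Per-piece rates and start volumes for exponential-family growth."""
        c = self.c
        if self.model.growth_law == "covariate_exponential":
            rate = params["beta"] - params["rho"] * c.pc_treat + params["delta"] * c.pc_obese
        else:
            rate = np.full(c.pc_a.shape, params["beta"])
        dt = c.pc_b - c.pc_a
        cum = np.cumsum(rate * dt)
        excl = np.concatenate([[0.0], cum[:-1]])
        log_s_a = np.log(params.get("S0", 0.065)) + excl - excl[c.pc_first[c.pc_pat]]
        return rate, dt, log_s_a

    def _obs_volumes(self, params, rate, log_s_a):
        c = self.c
        pieces = c.obs_piece
        return np.exp(
            log_s_a[pieces] + rate[pieces] * (c.obs_t - c.pc_a[pieces])
        )

    def _interval_quantities_closed(self, params, met, death):
        """Lambda, I_sqrtS, J*Lambda and end volumes, closed form."""
        c = self.c
        rate, dt, log_s_a = self._piece_arrays(params)
        s_a = np.exp(log_s_a)
        t_end = c.it_b[c.pc_itv]
        d = death.d_metas
        if met.kind == "volume":
            root_piece = np.sqrt(s_a) * dt * _expm1_ratio(rate * dt / 2.0)
            lam_piece = met.m_basal * dt + met.m_size * root_piece
            damp = np.exp(-d * (t_end - c.pc_a))
            jlam_piece = damp * (
                met.m_basal * dt * _expm1_ratio(d * dt)
                + met.m_size
                * np.sqrt(s_a)
                * dt
                * _expm1_ratio((rate / 2.0 + d) * dt)
            )
        else:
            ln2 = math.log(2.0)
            a_lo = (log_s_a - math.log(met.S_cell)) / ln2
            a_hi = a_lo + rate * dt / ln2
            k = int(met.k_exp)
            lam_piece = (
                met.m_division * ln2 / (k + 1.0) * (a_hi ** (k + 1) - a_lo ** (k + 1))
            )
            root_piece = np.sqrt(s_a) * dt * _expm1_ratio(rate * dt / 2.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                cexp = np.where(rate != 0.0, d * ln2 / np.where(rate == 0, 1.0, rate), 0.0)
            jlam_piece = np.where(
                rate != 0.0,
                met.m_division
                * ln2
                * np.exp(-d * (t_end - c.pc_a))
                * _poly_exp_integral(a_lo, a_hi, k, cexp),
                0.0,
            )
        n_itv = c.n_intervals
        lam = np.bincount(c.pc_itv, weights=lam_piece, minlength=n_itv)
        i_root = np.bincount(c.pc_itv, weights=root_piece, minlength=n_itv)
        jlam = np.bincount(c.pc_itv, weights=jlam_piece, minlength=n_itv)
        # end volume of each interval = its last piece grown to the end
        s_end = np.exp((log_s_a + rate * dt)[c.pc_last])
        s_obs_model = self._obs_volumes(params, rate, log_s_a)
        return lam, i_root, jlam, s_end, s_obs_model

    def _interval_quantities_quadrature(self, params, met, death, growth):
        """Same quantities via fixed-degree Clenshaw-Curtis rules on each
        interval (general growth laws); also returns the Chebyshev packs
        reused by the cubature route."""
        c = self.c
        flat_t = c.node_t.ravel()
        s_nodes = np.asarray(growth.volume(flat_t), dtype=float).reshape(c.node_t.shape)
        root_nodes = np.sqrt(s_nodes)
        if met.kind == "volume":
            lam_nodes = met.m_basal + met.m_size * root_nodes
        else:
            dv = np.asarray(growth.dvolume(flat_t), dtype=float).reshape(c.node_t.shape)
            a_nodes = (np.log(s_nodes) - math.log(met.S_cell)) / math.log(2.0)
            lam_nodes = met.m_division * a_nodes**met.k_exp * dv / s_nodes
        half = 0.5 * (c.it_b - c.it_a)
        w = _cc_weights(self.c._node_degree)
        lam = half * (lam_nodes @ w)
        i_root = half * (root_nodes @ w)
        weight = np.exp(-death.d_metas * (c.it_b[:, None] - c.node_t))
        jlam = half * ((lam_nodes * weight) @ w)
        s_end = np.asarray(growth.volume(c.it_b), dtype=float)
        s_obs_model = np.asarray(growth.volume(c.obs_t), dtype=float)
        packs = (lam_nodes, root_nodes)
        return lam, i_root, jlam, s_end, s_obs_model, packs

    # -- assembling the log-likelihood --------------------------------------
    def _assemble(self, params, death, lam, i_root, jlam, s_end, s_obs_model,
                  survival_logprob_obs=None):
        """Combine per-interval quantities into the total log-likelihood.

        ``survival_logprob_obs`` optionally overrides the log survival
        probability of observed-count intervals (used by the cubature
        route); everything else is shared.
        """
        c = self.c
        d = death.d_metas
        dt = c.it_b - c.it_a
        base_log = -params["d_size"] * i_root - d * c.i_n * dt
        lam = np.maximum(lam, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_j = np.where(lam > 0, np.log(np.maximum(jlam, 0.0)) - np.log(lam), 0.0)
        observed = c.i_m != c.MISSING
        m_obs = np.where(observed, c.i_m, 0).astype(float)

        met_ll = np.zeros(c.n_intervals)
        surv_ll = np.zeros(c.n_intervals)
        # observed-count intervals
        met_ll[observed] = metastasis_increment_loglik(lam[observed], m_obs[observed])
        if survival_logprob_obs is None:
            surv_obs = base_log[observed] + m_obs[observed] * log_j[observed]
        else:
            surv_obs = survival_logprob_obs
        death_obs = c.i_death[observed]
        lam_d_end = params["d_size"] * np.sqrt(s_end[observed]) + d * (
            c.i_n[observed] + m_obs[observed]
        )
        with np.errstate(divide="ignore"):
            surv_obs = surv_obs + np.where(death_obs, np.log(lam_d_end), 0.0)
        surv_ll[observed] = surv_obs
        # missing-count intervals
        miss = ~observed
        if np.any(miss):
            miss_death = miss & c.i_death
            miss_surv = miss & ~c.i_death
            # censored end: Poisson marginal exp(-(Lambda - J*Lambda))
            surv_ll[miss_surv] = base_log[miss_surv] - (
                lam[miss_surv] - np.maximum(jlam[miss_surv], 0.0)
            )
            if np.any(miss_death):
                idx = np.nonzero(miss_death)[0]
                mm = np.arange(self.c.M_max + 1)[None, :]
                with np.errstate(divide="ignore", invalid="ignore"):
                    log_pois = (
                        mm * np.log(lam[idx][:, None])
                        - lam[idx][:, None]
                        - gammaln(mm + 1.0)
                    )
                    log_pois = np.where((lam[idx][:, None] == 0) & (mm == 0), 0.0, log_pois)
                    log_pois = np.where(
                        (lam[idx][:, None] == 0) & (mm > 0), NEG_INF, log_pois
                    )
                    lam_d = params["d_size"] * np.sqrt(s_end[idx])[:, None] + d * (
                        c.i_n[idx][:, None] + mm
                    )
                    summand = log_pois + mm * log_j[idx][:, None] + np.log(lam_d)
                surv_ll[idx] = base_log[idx] + logsumexp(summand, axis=1)
        # observation terms
        sigma = params["sigma_S"]
        obs_ll = size_observation_loglik(
            s_obs_model, c.obs_v, sigma, self.model.noise_kind
        ) if c.obs_t.size else np.zeros(0)
        per_patient = (
            np.bincount(c.i_pat, weights=met_ll + surv_ll, minlength=c.n_patients)
            + np.bincount(c.obs_pat, weights=obs_ll, minlength=c.n_patients)
        )
        total = float(np.sum(met_ll) + np.sum(surv_ll) + np.sum(obs_ll))
        return LikelihoodValue(
            loglik=total if np.isfinite(total) else NEG_INF,
            observation=float(np.sum(obs_ll)),
            metastasis=float(np.sum(met_ll)),
            survival_death=float(np.sum(surv_ll)),
            per_patient=per_patient,
        )

    def loglik_value(self, theta, method: str = "auto") -> LikelihoodValue:
        params = self.model.params(theta)
        self.model.validate_theta(params)
        met = self.model.build_metastasis(params)
        death = self.model.build_death(params)
        if method == "auto":
            method = "closed_form" if self.closed_form_available else "quadrature"
        with np.errstate(over="ignore", invalid="ignore", divide="ignore", under="ignore"):
            if method == "closed_form":
                if not self.closed_form_available:
                    raise ValueError(
                        f"no closed-form likelihood for growth law "
                        f"{self.model.growth_law!r}"
                    )
                lam, i_root, jlam, s_end, s_obs = self._interval_quantities_closed(
                    params, met, death
                )
                return self._assemble(params, death, lam, i_root, jlam, s_end, s_obs)
            growth = self.model.build_growth(params)
            if self.model.growth_law == "covariate_exponential":
                raise ValueError(
                    "numeric routes for covariate growth evaluate per patient; "
                    "use method='closed_form'"
                )
            lam, i_root, jlam, s_end, s_obs, packs = self._interval_quantities_quadrature(
                params, met, death, growth
            )
            if method == "quadrature":
                return self._assemble(params, death, lam, i_root, jlam, s_end, s_obs)
            if method != "cubature":
                raise ValueError(f"unknown method {method!r}")
            lam_nodes, root_nodes = packs
            c = self.c
            lam_pack = _ChebPack(lam_nodes, c.it_a, c.it_b)
            g_pack = _ChebPack(root_nodes, c.it_a, c.it_b)
            observed = c.i_m != c.MISSING
            obs_idx = np.nonzero(observed)[0]
            log_surv = np.zeros(obs_idx.size)
            m_vals = c.i_m[obs_idx]
            for m in np.unique(m_vals):
                sel = obs_idx[m_vals == m]
                if m == 0:
                    haz = (
                        params["d_size"] * g_pack.total[sel]
                        + death.d_metas * c.i_n[sel] * (c.it_b[sel] - c.it_a[sel])
                    )
                    log_surv[m_vals == m] = -haz
                    continue
                n_1d = self._CUBATURE_NODES.get(int(m), 8)
                sub_lam = _ChebPack(lam_nodes[sel], c.it_a[sel], c.it_b[sel])
                sub_g = _ChebPack(root_nodes[sel], c.it_a[sel], c.it_b[sel])
                vals = _cubature_survival_batch(
                    sub_lam, sub_g, c.it_a[sel], c.it_b[sel], c.i_n[sel],
                    int(m), params["d_size"], death.d_metas, n_1d,
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    log_surv[m_vals == m] = np.log(np.maximum(vals, 0.0))
            return self._assemble(
                params, death, lam, i_root, jlam, s_end, s_obs,
                survival_logprob_obs=log_surv,
            )

    def negloglik(self, theta, method: str = "auto") -> float:
        ll = self.loglik_value(theta, method=method).loglik
        return math.inf if not np.isfinite(ll) else -ll


def patient_loglik(
    model: ModelSpec,
    theta,
    record: PatientRecord,
    method: str = "auto",
    M_max: Optional[int] = None,
) -> LikelihoodValue:
    """Log-likelihood of one patient record with per-term breakdown."""
    cohort = Cohort(records=[record])
    return CohortLikelihood(model, cohort, M_max=M_max).loglik_value(theta, method=method)


def cohort_negloglik(
    model: ModelSpec,
    theta,
    cohort: Cohort,
    method: str = "auto",
    M_max: Optional[int] = None,
) -> float:
    """Negative log-likelihood of a cohort (sum over independent patients).

    For repeated evaluations (optimisation, MCMC) build one
    :class:`CohortLikelihood` and reuse it; this convenience wrapper
    compiles the cohort afresh."""
    return CohortLikelihood(model, cohort, M_max=M_max).negloglik(theta, method=method)
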