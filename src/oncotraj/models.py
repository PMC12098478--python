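"""Model specifications and the M1-M5 study registry.

A :class:`ModelSpec` bundles a growth law, a metastasis-intensity kind, the
death intensity and an observation-noise model, together with the list of
free parameters, their log-scale bounds and the natural-scale values used
to generate synthetic cohorts.  The five shipped specifications combine:

====  ==================  =======================  =====================
name  growth              metastasis intensity     free parameters
====  ==================  =======================  =====================
m1    exponential         volume based             beta, m_basal, m_size,
                                                   d_size, d_metas
m2    exponential         cell-division based      beta, m_division,
                                                   d_size, d_metas
m3    Gompertz            volume based             beta, K, m_basal,
                                                   m_size, d_size, d_metas
m4    Gyllenberg-Webb     volume based             b, mu_q, m_basal,
                                                   m_size, d_size, d_metas
m5    exponential with    volume based             beta, rho, delta,
      treatment/obesity                            m_basal, m_size,
      covariates                                   d_size, d_metas
====  ==================  =======================  =====================

The death process is the same for all models.  All parameters are
positive and are handled on log scale during inference; the treatment
effect enters the growth rate as beta(t) = beta0 - rho*Z_treat(t) +
delta*Z_obese.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .growth import (
    CovariateEffect,
    CovariatePath,
    ExponentialGrowth,
    GompertzGrowth,
    GrowthModel,
    GyllenbergWebbGrowth,
    piecewise_exponential_from_covariates,
)
from .intensities import S_CELL_DEFAULT, DeathSpec, MetastasisSpec

__all__ = ["ModelSpec", "get_model", "MODELS", "GROWTH_LAWS"]

GROWTH_LAWS = ("exponential", "gompertz", "gyllenberg_webb", "covariate_exponential")


@dataclass
class ModelSpec:
    """A concrete combined-model parameterisation.

    ``free_names`` fixes the parameter ordering used by optimisers and
    samplers; ``log_bounds`` are (low, high) pairs on natural-log scale;
    ``fixed`` holds everything not estimated (detection volume ``S0``,
    noise scale ``sigma_S``, structural constants).
    """

    name: str
    growth_law: str
    metastasis_kind: str
    free_names: tuple
    log_bounds: dict
    true_theta: dict
    fixed: dict = field(default_factory=dict)
    noise_kind: str = "gaussian_proportional"
    include_dead: bool = False
    draw_covariates: Optional[Callable] = None
    _growth_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.growth_law not in GROWTH_LAWS:
            raise ValueError(f"unknown growth law {self.growth_law!r}")
        missing = [n for n in self.free_names if n not in self.log_bounds]
        if missing:
            raise ValueError(f"free parameters without bounds: {missing}")

    # -- parameter plumbing -------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.free_names)

    def params(self, theta=None) -> dict:
        """Merge free parameters (dict or array, natural scale) with the
        fixed ones; defaults to the generating values."""
        merged = dict(self.fixed)
        if theta is None:
            theta = self.true_theta
        if not isinstance(theta, dict):
            theta = self.theta_dict(theta)
        merged.update(theta)
        return merged

    def theta_array(self, theta: dict) -> np.ndarray:
        return np.array([float(theta[n]) for n in self.free_names])

    def theta_dict(self, arr) -> dict:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(self.free_names),):
            raise ValueError(
                f"expected {len(self.free_names)} parameters, got shape {arr.shape}"
            )
        return dict(zip(self.free_names, arr.tolist()))

    def log_bounds_arrays(self):
        lo = np.array([self.log_bounds[n][0] for n in self.free_names])
        hi = np.array([self.log_bounds[n][1] for n in self.free_names])
        return lo, hi

    def validate_theta(self, params: dict):
        for n in self.free_names:
            if not np.isfinite(params[n]) or params[n] < 0:
                raise ValueError(f"parameter {n} must be non-negative and finite")

    # -- component builders -------------------------------------------------
    def build_growth(self, params: dict, covariates: Optional[dict] = None) -> GrowthModel:
        s0 = params.get("S0", 0.065)
        if self.growth_law == "exponential":
            return ExponentialGrowth(S0=s0, beta=params["beta"])
        if self.growth_law == "gompertz":
            return GompertzGrowth(S0=s0, beta=params["beta"], K=params["K"])
        if self.growth_law == "gyllenberg_webb":
            key = tuple(
                params.get(k)
                for k in ("b", "mu_q", "d_clear", "r_coef", "k_coef", "a_coef", "m_coef", "S0")
            )
            if key not in self._growth_cache:
                self._growth_cache.clear()  # one live entry is enough
                self._growth_cache[key] = GyllenbergWebbGrowth(
                    b=params["b"],
                    mu_q=params["mu_q"],
                    d_clear=params.get("d_clear", 0.01),
                    r_coef=params.get("r_coef", 1.0),
                    k_coef=params.get("k_coef", 2.0),
                    a_coef=params.get("a_coef", 1.0),
                    m_coef=params.get("m_coef", 2.0),
                    P0=s0,
                    Q0=0.0,
                    R0=0.0,
                    include_dead=self.include_dead,
                )
            return self._growth_cache[key]
        # covariate-dependent exponential growth
        cov = covariates or {}
        obese = float(cov.get("obese", 0.0))
        t_rx = cov.get("treatment_start", None)
        eff = CovariateEffect(
            beta0=params["beta"], effects=(-params["rho"], params["delta"])
        )
        if t_rx is None or not np.isfinite(t_rx):
            path = CovariatePath.constant((0.0, obese))
        elif t_rx <= 0:
            path = CovariatePath.constant((1.0, obese))
        else:
            path = CovariatePath(times=(float(t_rx),), values=((0.0, obese), (1.0, obese)))
        return piecewise_exponential_from_covariates(s0, eff, path)

    def build_metastasis(self, params: dict) -> MetastasisSpec:
        if self.metastasis_kind == "volume":
            return MetastasisSpec(
                kind="volume",
                m_basal=params["m_basal"],
                m_size=params["m_size"],
                S_cell=params.get("S_cell", S_CELL_DEFAULT),
                N0=int(params.get("N0", 0)),
            )
        return MetastasisSpec(
            kind="cell_division",
            m_division=params["m_division"],
            k_exp=params.get("k_exp", 1.0),
            S_cell=params.get("S_cell", S_CELL_DEFAULT),
            N0=int(params.get("N0", 0)),
        )

    def build_death(self, params: dict) -> DeathSpec:
        return DeathSpec(d_size=params["d_size"], d_metas=params["d_metas"])


def _std_fixed(**extra) -> dict:
    fixed = {"S0": 0.065, "S_cell": S_CELL_DEFAULT, "sigma_S": 0.1, "N0": 0}
    fixed.update(extra)
    return fixed


def _draw_treatment_covariates(rng: np.random.Generator) -> dict:
    """Randomised treatment assignment: half the cohort starts a permanent
    treatment at a uniform time in the first year; 30% of patients are
    obese throughout."""
    treated = rng.random() < 0.5
    return {
        "treatment_start": float(rng.uniform(0.0, 12.0)) if treated else None,
        "obese": int(rng.random() < 0.3),
    }


def _m1() -> ModelSpec:
    return ModelSpec(
        name="m1",
        growth_law="exponential",
        metastasis_kind="volume",
        free_names=("beta", "m_basal", "m_size", "d_size", "d_metas"),
        log_bounds={
            "beta": (-0.75, -0.65),
            "m_basal": (-7.0, -2.0),
            "m_size": (-7.0, -2.0),
            "d_size": (-9.0, -4.0),
            "d_metas": (-9.0, -4.0),
        },
        true_theta={
            "beta": math.exp(-0.693),
            "m_basal": math.exp(-4.605),
            "m_size": math.exp(-6.908),
            "d_size": math.exp(-8.1117),
            "d_metas": math.exp(-5.809),
        },
        fixed=_std_fixed(),
    )


def _m2() -> ModelSpec:
    return ModelSpec(
        name="m2",
        growth_law="exponential",
        metastasis_kind="cell_division",
        free_names=("beta", "m_division", "d_size", "d_metas"),
        log_bounds={
            "beta": (-0.75, -0.65),
            "m_division": (-7.0, -2.0),
            "d_size": (-9.0, -4.0),
            "d_metas": (-9.0, -4.0),
        },
        true_theta={
            "beta": math.exp(-0.693),
            "m_division": 0.005,
            "d_size": math.exp(-8.1117),
            "d_metas": math.exp(-5.809),
        },
        fixed=_std_fixed(k_exp=1.0),
    )


def _m3() -> ModelSpec:
    return ModelSpec(
        name="m3",
        growth_law="gompertz",
        metastasis_kind="volume",
        free_names=("beta", "K", "m_basal", "m_size", "d_size", "d_metas"),
        log_bounds={
            "beta": (-2.3, -0.7),
            "K": (10.8, 13.0),
            "m_basal": (-7.0, -2.0),
            "m_size": (-7.0, -2.0),
            "d_size": (-9.0, -4.0),
            "d_metas": (-9.0, -4.0),
        },
        true_theta={
            "beta": 0.2,
            "K": 150000.0,  # 150 cm^3
            "m_basal": math.exp(-4.605),
            "m_size": math.exp(-6.908),
            "d_size": math.exp(-8.1117),
            "d_metas": math.exp(-5.809),
        },
        fixed=_std_fixed(),
    )


def _m4() -> ModelSpec:
    return ModelSpec(
        name="m4",
        growth_law="gyllenberg_webb",
        metastasis_kind="volume",
        free_names=("b", "mu_q", "m_basal", "m_size", "d_size", "d_metas"),
        log_bounds={
            "b": (-1.6, 0.7),
            "mu_q": (-5.0, -1.0),
            "m_basal": (-7.0, -1.0),
            "m_size": (-5.0, -0.5),
            "d_size": (-7.0, -1.0),
            "d_metas": (-7.0, -1.0),
        },
        true_theta={
            "b": 1.0,
            "mu_q": 0.05,
            "m_basal": 0.05,
            "m_size": 0.1,
            "d_size": 0.01,
            "d_metas": 0.03,
        },
        fixed=_std_fixed(d_clear=0.01, r_coef=1.0, k_coef=2.0, a_coef=1.0, m_coef=2.0),
    )


def _m5() -> ModelSpec:
    return ModelSpec(
        name="m5",
        growth_law="covariate_exponential",
        metastasis_kind="volume",
        free_names=("beta", "rho", "delta", "m_basal", "m_size", "d_size", "d_metas"),
        log_bounds={
            "beta": (-0.75, -0.65),
            "rho": (-0.85, -0.75),
            "delta": (-2.3, -1.2),
            "m_basal": (-7.0, -2.0),
            "m_size": (-7.0, -2.0),
            "d_size": (-9.0, -4.0),
            "d_metas": (-9.0, -4.0),
        },
        true_theta={
            "beta": math.exp(-0.693),
            "rho": math.exp(-0.799),
            "delta": math.exp(-1.609),
            "m_basal": math.exp(-4.605),
            "m_size": math.exp(-6.908),
            "d_size": math.exp(-8.1117),
            "d_metas": math.exp(-5.809),
        },
        fixed=_std_fixed(),
        draw_covariates=_draw_treatment_covariates,
    )


MODELS = {"m1": _m1, "m2": _m2, "m3": _m3, "m4": _m4, "m5": _m5}


def get_model(name: str) -> ModelSpec:
    """Fresh :class:`ModelSpec` for one of the registered models m1-m5."""
    try:
        return MODELS[name.lower()]()
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODELS)}")
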