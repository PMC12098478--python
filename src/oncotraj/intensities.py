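"""Metastasis and death intensities with their cumulative integrals.

The metastasis count N(t) is an inhomogeneous Poisson process whose
intensity couples to the tumour volume S(t).  Two parameterisations are
supported:

``volume``
    lambda_N(t) = m_basal + m_size * sqrt(S(t)) -- a basal seeding rate
    plus a size-driven term,
``cell_division``
    lambda_N(t) = m_division * A(t)^k * S'(t)/S(t) with
    A(t) = (ln S(t) - ln S_cell)/ln 2, the number of cell divisions since
    the single-cell origin (S'/S = ln 2 * A' is the relative growth
    rate).  Because the integrand is a perfect derivative, the cumulative
    intensity is closed-form for any growth law:
    Lambda = m_division * ln2/(k+1) * (A(t_b)^{k+1} - A(t_a)^{k+1}),
    which for exponential growth from the single cell reduces to
    m_division * beta^{k+1} (t_b^{k+1} - t_a^{k+1}) / ((k+1) ln2^k).

The death process is a first-jump-stopped Poisson process with

    lambda_D(t) = d_size * sqrt(S(t)) + d_metas * N(t),

i.e. an exponential-survival hazard driven by tumour burden and
metastatic load.

Cumulative intensities use printed closed forms for exponential growth
and adaptive Clenshaw-Curtis quadrature (relative tolerance 1e-8)
otherwise.  Inversion of cumulative intensities -- the primitive the
next-reaction simulator needs -- is closed-form where available and
bracketed root-finding elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .growth import (
    ExponentialGrowth,
    GrowthModel,
    PiecewiseExponentialGrowth,
    sphere_volume,
)
from .quadrature import cc_quad

__all__ = [
    "MetastasisSpec",
    "DeathSpec",
    "metastasis_intensity",
    "cumulative_metastasis_intensity",
    "invert_cumulative_intensity",
    "death_intensity",
    "cumulative_death_intensity",
    "sqrt_volume_integral",
]

S_CELL_DEFAULT = sphere_volume(0.01)  # volume of a 0.01 mm-diameter cell, mm^3

_REL_TOL = 1e-8
_ABS_TOL = 1e-12


@dataclass(frozen=True)
class MetastasisSpec:
    """Parameters of the metastatic seeding intensity.

    ``kind`` selects the parameterisation ('volume' or 'cell_division');
    unused rate parameters are ignored.  ``N0`` is the metastasis count at
    detection.
    """

    kind: str = "volume"
    m_basal: float = 0.0
    m_size: float = 0.0
    m_division: float = 0.0
    k_exp: float = 1.0
    S_cell: float = S_CELL_DEFAULT
    N0: int = 0

    def __post_init__(self):
        if self.kind not in ("volume", "cell_division"):
            raise ValueError(f"unknown metastasis kind {self.kind!r}")
        for name in ("m_basal", "m_size", "m_division"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_exp < 1:
            raise ValueError("k_exp must be >= 1")
        if self.S_cell <= 0:
            raise ValueError("S_cell must be positive")
        if self.N0 < 0:
            raise ValueError("N0 must be non-negative")


@dataclass(frozen=True)
class DeathSpec:
    """Parameters of the death intensity lambda_D = d_size*sqrt(S) + d_metas*N."""

    d_size: float = 0.0
    d_metas: float = 0.0

    def __post_init__(self):
        if self.d_size < 0 or self.d_metas < 0:
            raise ValueError("death rates must be non-negative")


def _divisions(spec: MetastasisSpec, growth: GrowthModel, t):
    s = np.asarray(growth.volume(t), dtype=float)
    if np.any(s < spec.S_cell * (1.0 - 1e-12)):
        raise ValueError("tumour volume below the single-cell volume S_cell")
    return (np.log(np.maximum(s, spec.S_cell)) - math.log(spec.S_cell)) / math.log(2.0)


def metastasis_intensity(spec: MetastasisSpec, growth: GrowthModel, t):
    """lambda_N(t, S(t)); vectorised over t."""
    t = np.asarray(t, dtype=float)
    if spec.kind == "volume":
        return spec.m_basal + spec.m_size * np.sqrt(growth.volume(t))
    a = _divisions(spec, growth, t)
    rel_rate = np.asarray(growth.dvolume(t), dtype=float) / np.asarray(
        growth.volume(t), dtype=float
    )
    return spec.m_division * a**spec.k_exp * rel_rate


def _expm1_ratio(x):
    """(e^x - 1)/x, stable near 0; vectorised."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 + x / 2.0, np.expm1(safe) / safe)


def sqrt_volume_integral(growth: GrowthModel, t_a: float, t_b: float) -> float:
    """int_{t_a}^{t_b} sqrt(S(s)) ds; closed form for (piecewise) exponential
    growth, adaptive quadrature otherwise."""
    if t_b < t_a:
        raise ValueError("need t_b >= t_a")
    if t_b == t_a:
        return 0.0
    if isinstance(growth, ExponentialGrowth):
        pieces = [(t_a, t_b, float(growth.volume(t_a)), growth.beta)]
    elif isinstance(growth, PiecewiseExponentialGrowth):
        pieces = growth.pieces_between(t_a, t_b)
    else:
        return cc_quad(
            lambda t: np.sqrt(growth.volume(t)), t_a, t_b, _REL_TOL, _ABS_TOL
        )
    total = 0.0
    for a, b, s_a, beta in pieces:
        dt = b - a
        total += math.sqrt(s_a) * dt * float(_expm1_ratio(beta * dt / 2.0))
    return total


def cumulative_metastasis_intensity(
    spec: MetastasisSpec, growth: GrowthModel, t_a: float, t_b: float
) -> float:
    """Lambda_N([t_a, t_b)) = int lambda_N dt (>= 0, additive over intervals)."""
    if t_b < t_a:
        raise ValueError("need t_b >= t_a")
    if t_b == t_a:
        return 0.0
    if spec.kind == "volume":
        return spec.m_basal * (t_b - t_a) + spec.m_size * sqrt_volume_integral(
            growth, t_a, t_b
        )
    # cell-division kind: lambda = m_div A^k (ln2 A') is a perfect derivative
    a_lo = float(_divisions(spec, growth, t_a))
    a_hi = float(_divisions(spec, growth, t_b))
    k1 = spec.k_exp + 1.0
    return spec.m_division * math.log(2.0) / k1 * (a_hi**k1 - a_lo**k1)


def invert_cumulative_intensity(
    spec: MetastasisSpec,
    growth: GrowthModel,
    t_a: float,
    target: float,
    t_cap: float = 1e6,
    tol: float = 1e-10,
) -> float:
    """Smallest t >= t_a with Lambda_N([t_a, t)) = target.

    Returns ``inf`` when the cumulative intensity never reaches ``target``
    before ``t_cap`` (e.g. all rates zero).  Root-finding tolerance 1e-10.
    """
    if target < 0:
        raise ValueError("target must be non-negative")
    if target == 0.0:
        return t_a
    hi = t_a + 1.0
    while True:
        lam = cumulative_metastasis_intensity(spec, growth, t_a, hi)
        if lam >= target:
            break
        if hi >= t_cap:
            return math.inf
        hi = min(t_a + (hi - t_a) * 2.0, t_cap)
    return brentq(
        lambda t: cumulative_metastasis_intensity(spec, growth, t_a, t) - target,
        t_a,
        hi,
        xtol=tol,
        rtol=1e-15,
    )


def death_intensity(spec: DeathSpec, growth: GrowthModel, t, n):
    """lambda_D(t, S(t), n) for metastasis count n (vectorised)."""
    n = np.asarray(n)
    if np.any(n < 0) or not np.all(np.equal(np.mod(n, 1), 0)):
        raise ValueError("metastasis count must be a non-negative integer")
    return spec.d_size * np.sqrt(growth.volume(t)) + spec.d_metas * np.asarray(
        n, dtype=float
    )


def cumulative_death_intensity(spec: DeathSpec, growth: GrowthModel, segments):
    """Integrated death hazard over ordered segments (t_start, t_end, n).

    Each segment carries a constant metastasis count n; contributions are
    d_size * int sqrt(S) + d_metas * n * (t_end - t_start), summed.
    """
    total = 0.0
    prev_end = None
    for t0, t1, n in segments:
        if t1 < t0:
            raise ValueError("segment end before start")
        if prev_end is not None and t0 < prev_end - 1e-12:
            raise ValueError("segments overlap")
        if n < 0 or n != int(n):
            raise ValueError("metastasis count must be a non-negative integer")
        total += spec.d_size * sqrt_volume_integral(growth, t0, t1)
        total += spec.d_metas * n * (t1 - t0)
        prev_end = t1
    return total


def invert_cumulative_death_intensity(
    spec: DeathSpec,
    growth: GrowthModel,
    segments,
    target: float,
    tol: float = 1e-10,
):
    """First time the integrated death hazard along ``segments`` reaches
    ``target``; ``inf`` if it never does within the segments."""
    if target < 0:
        raise ValueError("target must be non-negative")
    acc = 0.0
    for t0, t1, n in segments:
        seg = cumulative_death_intensity(spec, growth, [(t0, t1, n)])
        if acc + seg >= target and seg > 0:
            want = target - acc
            return brentq(
                lambda t: cumulative_death_intensity(spec, growth, [(t0, t, n)])
                - want,
                t0,
                t1,
                xtol=tol,
                rtol=1e-15,
            )
        acc += seg
    return math.inf
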