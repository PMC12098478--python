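"""Exact simulation of patient trajectories and the clinical observation model.

Latent trajectories are drawn with a next-reaction scheme: unit-rate
exponential increments are inverted through the cumulative metastasis
intensity to give exact jump times of the inhomogeneous Poisson seeding
process, and the death time comes from inverting the integrated death
hazard along the piecewise-constant metastasis path.  This is exact for
unbounded intensities (where thinning would fail) and reproducible from a
seed via per-patient substreams.

Observations mimic a clinical study: monthly visits (noisy tumour volume,
exact metastasis count) until death or the end of follow-up; death is
observed at its exact time and recorded as a final visit row without a
size measurement.  ``mask_missing`` degrades a cohort the way messy
registry data would: dropped visits and missing size/count fields, never
touching a death row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np

from .growth import GrowthModel
from .intensities import (
    S_CELL_DEFAULT,
    invert_cumulative_death_intensity,
    invert_cumulative_intensity,
)
from .models import ModelSpec

__all__ = [
    "StudyDesign",
    "LatentTrajectory",
    "PatientRecord",
    "Cohort",
    "simulate_patient",
    "observe_patient",
    "simulate_cohort",
    "mask_missing",
]


@dataclass(frozen=True)
class StudyDesign:
    """Observation design of the simulated study.

    Defaults follow the simulation study: monthly visits over a 30-month
    horizon, detection at the volume of a 0.5 mm sphere (0.065 mm^3),
    tumours originating from a single 0.01 mm cell, zero metastases at
    detection, and proportional Gaussian size noise with sigma_S = 0.1.
    """

    visit_interval: float = 1.0
    t_max: float = 30.0
    S_detection: float = 0.065
    S_cell: float = S_CELL_DEFAULT
    N0: int = 0
    noise_kind: str = "gaussian_proportional"
    sigma_S: float = 0.1

    def __post_init__(self):
        if self.visit_interval <= 0 or self.t_max <= 0:
            raise ValueError("visit_interval and t_max must be positive")
        if not (0 < self.S_cell < self.S_detection):
            raise ValueError("need 0 < S_cell < S_detection")
        if self.noise_kind not in ("gaussian_proportional", "lognormal"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")


@dataclass
class LatentTrajectory:
    """Simulated ground truth for one patient."""

    growth: GrowthModel
    metastasis_times: np.ndarray
    death_time: Optional[float]  # None = alive (censored) at t_max
    t_max: float
    N0: int = 0
    covariates: Optional[dict] = None

    def n_at(self, t):
        """Metastasis count N(t) (right-continuous)."""
        return self.N0 + np.searchsorted(self.metastasis_times, t, side="right")


@dataclass
class PatientRecord:
    """Visit-level observations for one patient.

    ``size_obs`` and ``n_metastases`` use NaN for missing entries; the
    ``death`` column is 1 only on the final row and only when the death
    time itself is the row time.
    """

    patient_id: str
    times: np.ndarray
    size_obs: np.ndarray
    n_metastases: np.ndarray
    death: np.ndarray
    covariates: Optional[dict] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.size_obs = np.asarray(self.size_obs, dtype=float)
        self.n_metastases = np.asarray(self.n_metastases, dtype=float)
        self.death = np.asarray(self.death, dtype=int)
        self.validate()

    def validate(self):
        t = self.times
        if t.ndim != 1 or any(
            arr.shape != t.shape for arr in (self.size_obs, self.n_metastases, self.death)
        ):
            raise ValueError("row arrays must be 1-d and of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"visit times must be strictly increasing (patient {self.patient_id})")
        obs = self.n_metastases[~np.isnan(self.n_metastases)]
        if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
            raise ValueError(f"metastasis counts must be non-negative integers (patient {self.patient_id})")
        if obs.size and np.any(np.diff(obs) < 0):
            raise ValueError(f"observed metastasis counts decrease (patient {self.patient_id})")
        ndeath = int(np.sum(self.death == 1))
        if ndeath > 1 or (ndeath == 1 and self.death[-1] != 1):
            raise ValueError(f"death row must be unique and last (patient {self.patient_id})")

    @property
    def died(self) -> bool:
        return self.death.size > 0 and self.death[-1] == 1


@dataclass
class Cohort:
    """A list of patient records plus provenance (true parameters, seed,
    design) when simulated."""

    records: List[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def simulate_patient(
    model: ModelSpec,
    theta,
    design: StudyDesign,
    rng: np.random.Generator,
    covariates: Optional[dict] = None,
) -> LatentTrajectory:
    """Draw one latent trajectory by next-reaction inversion.

    Metastasis jump times solve Lambda_N([t_k, t)) = E_k with E_k ~ Exp(1);
    the death time solves the analogous equation for the integrated death
    hazard along the realised piecewise-constant metastasis path.  The
    trajectory is truncated at death or ``design.t_max``.
    """
    params = model.params(theta)
    model.validate_theta(params)
    growth = model.build_growth(params, covariates)
    met = model.build_metastasis(params)
    death = model.build_death(params)

    # metastasis jumps over the full horizon
    jumps = []
    t = 0.0
    while True:
        target = rng.exponential()
        t = invert_cumulative_intensity(met, growth, t, target, t_cap=design.t_max * 1.01)
        if not math.isfinite(t) or t >= design.t_max:
            break
        jumps.append(t)

    # death along the piecewise-constant count path
    edges = [0.0] + jumps + [design.t_max]
    segments = [
        (edges[i], edges[i + 1], design.N0 + i) for i in range(len(edges) - 1)
    ]
    t_death = invert_cumulative_death_intensity(death, growth, segments, rng.exponential())
    if not math.isfinite(t_death) or t_death >= design.t_max:
        t_death = None
        kept = jumps
    else:
        kept = [u for u in jumps if u < t_death]
    return LatentTrajectory(
        growth=growth,
        metastasis_times=np.asarray(kept, dtype=float),
        death_time=t_death,
        t_max=design.t_max,
        N0=design.N0,
        covariates=covariates,
    )


def _noisy_sizes(s_true: np.ndarray, design: StudyDesign, rng: np.random.Generator):
    z = rng.standard_normal(s_true.shape)
    if design.noise_kind == "gaussian_proportional":
        return s_true * (1.0 + design.sigma_S * z)
    return s_true * np.exp(design.sigma_S * z)


def observe_patient(
    traj: LatentTrajectory,
    design: StudyDesign,
    rng: np.random.Generator,
    patient_id: str = "p0",
) -> PatientRecord:
    """Read the latent trajectory out at scheduled visits.

    Rows appear at 0, dt, 2dt, ... strictly before death (or up to t_max
    for survivors), plus a final row at the exact death time carrying
    death=1 and no size measurement (death is observed directly, the
    tumour size is not re-measured at that moment).
    """
    if traj.death_time is None:
        visits = np.arange(0.0, traj.t_max + 1e-9, design.visit_interval)
        t_rows = visits
    else:
        visits = np.arange(0.0, traj.death_time - 1e-12, design.visit_interval)
        t_rows = np.append(visits, traj.death_time)
    s_true = np.asarray(traj.growth.volume(t_rows), dtype=float)
    size_obs = _noisy_sizes(s_true, design, rng)
    n_obs = traj.n_at(t_rows).astype(float)
    death = np.zeros(t_rows.shape, dtype=int)
    if traj.death_time is not None:
        size_obs[-1] = np.nan
        death[-1] = 1
    return PatientRecord(
        patient_id=patient_id,
        times=t_rows,
        size_obs=size_obs,
        n_metastases=n_obs,
        death=death,
        covariates=traj.covariates,
    )


def simulate_cohort(
    model: ModelSpec,
    n_patients: int,
    design: Optional[StudyDesign] = None,
    theta=None,
    seed: int = 0,
) -> Cohort:
    """Simulate an independent cohort, reproducible from ``seed``.

    Per-patient random substreams are spawned from a single seed sequence
    so cohorts are identical regardless of generation order.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    design = design or StudyDesign()
    theta_dict = model.params(theta)
    free = {n: theta_dict[n] for n in model.free_names}
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    records = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cov = model.draw_covariates(rng) if model.draw_covariates else None
        traj = simulate_patient(model, free, design, rng, covariates=cov)
        records.append(observe_patient(traj, design, rng, patient_id=f"p{i:04d}"))
    provenance = {
        "model": model.name,
        "theta": free,
        "seed": int(seed),
        "n_patients": int(n_patients),
        "design": asdict(design),
    }
    return Cohort(records=records, provenance=provenance)


def mask_missing(
    cohort: Cohort,
    p_visit_drop: float = 0.0,
    p_size_miss: float = 0.0,
    p_met_miss: float = 0.0,
    seed: int = 0,
) -> Cohort:
    """Degrade a cohort with missingness.

    Non-death rows are dropped with probability ``p_visit_drop``; surviving
    rows lose their size / metastasis measurements with the respective
    probabilities.  Death rows are never dropped and their death indicator
    is never masked, so survival status is known whenever a row exists.
    """
    for p in (p_visit_drop, p_size_miss, p_met_miss):
        if not 0.0 <= p <= 1.0:
            raise ValueError("missingness fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for rec in cohort:
        keep = rng.random(rec.times.shape) >= p_visit_drop
        keep |= rec.death == 1
        times = rec.times[keep]
        size = rec.size_obs[keep].copy()
        nmet = rec.n_metastases[keep].copy()
        death = rec.death[keep]
        size[rng.random(size.shape) < p_size_miss] = np.nan
        nmet[rng.random(nmet.shape) < p_met_miss] = np.nan
        records.append(
            PatientRecord(
                patient_id=rec.patient_id,
                times=times,
                size_obs=size,
                n_metastases=nmet,
                death=death,
                covariates=rec.covariates,
            )
        )
    provenance = dict(cohort.provenance)
    provenance["masking"] = {
        "p_visit_drop": p_visit_drop,
        "p_size_miss": p_size_miss,
        "p_met_miss": p_met_miss,
        "seed": int(seed),
    }
    return Cohort(records=records, provenance=provenance)
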