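"""Cohort file formats and run configuration.

Cohorts are stored in long format: one CSV row per visit with columns
``patient_id, time, size_obs, n_metastases, death`` plus covariate
columns, empty cells meaning missing.  A sidecar ``<path>.meta.json``
carries provenance (generating parameters, seed, study design) and the
exact covariate paths (treatment start times are real numbers, which the
0/1 indicator columns cannot represent losslessly).  An equivalent
single-file JSON format embeds both.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import Cohort, PatientRecord

__all__ = ["read_cohort", "write_cohort", "cohort_to_frame", "read_config"]

_COLUMNS = ["patient_id", "time", "size_obs", "n_metastases", "death"]


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame view of a cohort (one row per visit)."""
    rows = []
    for rec in cohort:
        cov = rec.covariates or {}
        t_rx = cov.get("treatment_start")
        for j in range(rec.times.size):
            row = {
                "patient_id": rec.patient_id,
                "time": rec.times[j],
                "size_obs": rec.size_obs[j],
                "n_metastases": rec.n_metastases[j],
                "death": int(rec.death[j]),
            }
            if cov:
                row["treatment"] = int(
                    t_rx is not None
                    and np.isfinite(t_rx)
                    and rec.times[j] >= t_rx - 1e-12
                )
                row["obese"] = int(cov.get("obese", 0))
            rows.append(row)
    cols = _COLUMNS + (
        ["treatment", "obese"] if any(r.covariates for r in cohort) else []
    )
    return pd.DataFrame(rows, columns=cols)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as long-format CSV (+ provenance sidecar) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "provenance": _jsonable(cohort.provenance),
            "patients": [
                {
                    "patient_id": rec.patient_id,
                    "times": rec.times.tolist(),
                    "size_obs": [None if np.isnan(v) else v for v in rec.size_obs],
                    "n_metastases": [
                        None if np.isnan(v) else int(v) for v in rec.n_metastases
                    ],
                    "death": rec.death.tolist(),
                    "covariates": _jsonable(rec.covariates) if rec.covariates else None,
                }
                for rec in cohort
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    frame = cohort_to_frame(cohort)
    frame.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "provenance": _jsonable(cohort.provenance),
        "covariates": {
            rec.patient_id: _jsonable(rec.covariates)
            for rec in cohort
            if rec.covariates
        },
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def _record_from_arrays(pid, times, size, nmet, death, covariates):
    return PatientRecord(
        patient_id=str(pid),
        times=np.asarray(times, dtype=float),
        size_obs=np.asarray(
            [np.nan if v is None else float(v) for v in size], dtype=float
        ),
        n_metastases=np.asarray(
            [np.nan if v is None else float(v) for v in nmet], dtype=float
        ),
        death=np.asarray(death, dtype=int),
        covariates=covariates,
    )


def read_cohort(path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`; validates all patient
    invariants (monotone times, non-decreasing counts, death row last)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        records = [
            _record_from_arrays(
                p["patient_id"],
                p["times"],
                p["size_obs"],
                p["n_metastases"],
                p["death"],
                p.get("covariates"),
            )
            for p in payload["patients"]
        ]
        return Cohort(records=records, provenance=payload.get("provenance", {}))
    frame = pd.read_csv(path)
    missing_cols = [c for c in _COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"cohort file lacks required columns: {missing_cols}")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    cov_map = meta.get("covariates", {})
    records = []
    for pid, grp in frame.groupby("patient_id", sort=False):
        cov = cov_map.get(str(pid))
        if cov is None and "treatment" in frame.columns:
            # reconstruct covariates from indicator columns (start time is
            # approximated by the first treated visit)
            treated = grp["treatment"].to_numpy() > 0
            cov = {
                "treatment_start": float(grp["time"].to_numpy()[treated][0])
                if treated.any()
                else None,
                "obese": int(grp["obese"].iloc[0]),
            }
        try:
            records.append(
                _record_from_arrays(
                    pid,
                    grp["time"].to_numpy(),
                    grp["size_obs"].to_numpy(),
                    grp["n_metastases"].to_numpy(),
                    grp["death"].fillna(0).to_numpy(),
                    cov,
                )
            )
        except ValueError as err:
            rows = ", ".join(str(i + 2) for i in grp.index[:5])  # 1-based + header
            raise ValueError(f"invalid patient {pid!r} (rows {rows}): {err}") from err
    return Cohort(records=records, provenance=meta.get("provenance", {}))


def read_config(path) -> dict:
    """YAML run configuration: model/design/inference blocks."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
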