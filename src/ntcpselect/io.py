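"""Tabular file formats: cumulative-DVH CSV and patient covariate CSV.

DVH files carry one row per (patient, plan, structure, dose point) with
columns ``patient_id, plan, structure, total_volume_cc, dose_gy,
cum_volume_fraction``; dose is ascending within each structure and values
round-trip within 1e-9.  Covariate files carry one row per patient with the
clinical covariates, the semicolon-joined prescription levels, and any named
model covariates as ``cov_<name>`` columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dvh import StructureDVH
from .records import PatientCovariates, PlanRecord, PrescriptionLevel

__all__ = [
    "DVH_COLUMNS",
    "write_dvh_csv",
    "read_dvh_csv",
    "write_covariates_csv",
    "read_covariates_csv",
]

DVH_COLUMNS = [
    "patient_id", "plan", "structure", "total_volume_cc", "dose_gy",
    "cum_volume_fraction",
]

_TARGET_ORDER = ["ptv_hd", "ptv_id", "ptv_ld"]


def write_dvh_csv(plans: list[PlanRecord], path: str | Path) -> None:
    """Write plans as cumulative-DVH CSV (12 significant digits)."""
    frames = []
    for plan in plans:
        for name, dvh in plan.structures.items():
            c = dvh.to_cumulative()
            frames.append(pd.DataFrame({
                "patient_id": plan.patient_id,
                "plan": plan.modality,
                "structure": name,
                "total_volume_cc": c.total_volume_cc,
                "dose_gy": c.dose_gy,
                "cum_volume_fraction": c.volume,
            }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.12g")


def read_dvh_csv(
    path: str | Path,
    prescriptions: dict[str, list[PrescriptionLevel]] | None = None,
) -> list[PlanRecord]:
    """Read a DVH CSV back into plan records.

    ``prescriptions`` optionally maps patient_id to prescription levels
    (e.g. as parsed from a covariate file); without it plans carry none.
    """
    df = pd.read_csv(path)
    missing = [c for c in DVH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DVH columns {missing}")
    plans = []
    for (pid, modality), g in df.groupby(["patient_id", "plan"], sort=True):
        structures = {}
        for sname, sg in g.groupby("structure", sort=True):
            dose = sg["dose_gy"].to_numpy()
            if np.any(np.diff(dose) <= 0):
                first_bad = int(np.argmax(np.diff(dose) <= 0))
                raise ValueError(
                    f"{path}: dose not ascending for {pid}/{modality}/{sname} "
                    f"near row {sg.index[first_bad] + 2}"
                )
            structures[sname] = StructureDVH.from_cumulative(
                sname,
                float(sg["total_volume_cc"].iloc[0]),
                dose,
                sg["cum_volume_fraction"].to_numpy(),
            )
        levels = (prescriptions or {}).get(str(pid), [])
        plans.append(PlanRecord(str(pid), str(modality), list(levels), structures))
    return plans


def write_covariates_csv(
    covariates: list[PatientCovariates],
    path: str | Path,
    prescriptions: dict[str, list[PrescriptionLevel]] | None = None,
) -> None:
    rows = []
    extra_names = sorted({k for c in covariates for k in c.extra})
    for c in covariates:
        row = {
            "patient_id": c.patient_id,
            "age": c.age,
            "t_stage": c.t_stage,
            "n_stage": c.n_stage,
            "overall_stage": c.overall_stage,
            "treatment": c.treatment,
        }
        levels = (prescriptions or {}).get(c.patient_id, [])
        row["rx_targets"] = ";".join(p.target_id for p in levels)
        row["rx_doses_gy"] = ";".join(f"{p.dose_gy:g}" for p in levels)
        row["rx_fractions"] = levels[0].fractions if levels else ""
        for name in extra_names:
            row[f"cov_{name}"] = c.extra.get(name, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_covariates_csv(
    path: str | Path,
) -> tuple[list[PatientCovariates], dict[str, list[PrescriptionLevel]]]:
    df = pd.read_csv(path)
    covs, rx = [], {}
    for _, row in df.iterrows():
        extra = {
            col[len("cov_"):]: float(row[col])
            for col in df.columns if col.startswith("cov_") and pd.notna(row[col])
        }
        covs.append(PatientCovariates(
            patient_id=str(row["patient_id"]),
            age=float(row["age"]),
            t_stage=int(row["t_stage"]),
            n_stage=int(row["n_stage"]),
            overall_stage=str(row["overall_stage"]),
            treatment=str(row["treatment"]),
            extra=extra,
        ))
        if pd.notna(row.get("rx_targets")) and str(row["rx_targets"]):
            targets = str(row["rx_targets"]).split(";")
            doses = [float(x) for x in str(row["rx_doses_gy"]).split(";")]
            fx = int(row["rx_fractions"]) if pd.notna(row.get("rx_fractions")) else 33
            rx[str(row["patient_id"])] = [
                PrescriptionLevel(t, d, fx) for t, d in zip(targets, doses)
            ]
    return covs, rx
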