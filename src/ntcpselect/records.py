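"""Patient-level domain records: plans and clinical covariates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .dvh import StructureDVH

__all__ = ["PrescriptionLevel", "PlanRecord", "PatientCovariates", "TREATMENTS"]

TREATMENTS = ("RT alone", "RT-CHT", "iCHT+RT-CHT")

Modality = Literal["photon", "proton"]


@dataclass(frozen=True)
class PrescriptionLevel:
    """One prescription dose level, e.g. 69.96 Gy(RBE) in 33 fractions to the PTV-HD."""

    target_id: str
    dose_gy: float
    fractions: int = 33


@dataclass
class PlanRecord:
    """A single patient's plan for one modality: structures plus prescriptions."""

    patient_id: str
    modality: Modality
    prescription_levels: list[PrescriptionLevel]
    structures: dict[str, StructureDVH]
    body_volume_cc: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("photon", "proton"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.body_volume_cc is None and "body" in self.structures:
            self.body_volume_cc = self.structures["body"].total_volume_cc

    def prescription_for(self, target_id: str) -> float | None:
        for level in self.prescription_levels:
            if level.target_id == target_id:
                return level.dose_gy
        return None


@dataclass
class PatientCovariates:
    """Clinical covariates entering stratification and covariate-bearing models.

    ``extra`` carries named numeric covariates required by individual NTCP
    models (e.g. a concurrent-chemotherapy indicator).
    """

    patient_id: str
    age: float
    t_stage: int
    n_stage: int
    overall_stage: str
    treatment: str
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_stage not in (1, 2, 3, 4):
            raise ValueError(f"T stage must be 1-4, got {self.t_stage}")
        if self.n_stage not in (0, 1, 2, 3):
            raise ValueError(f"N stage must be 0-3, got {self.n_stage}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")

    @property
    def t_group(self) -> str:
        return "T1-T2" if self.t_stage <= 2 else "T3-T4"

    @property
    def n_group(self) -> str:
        return {0: "N0", 1: "N1"}.get(self.n_stage, "N2-N3")

    def covariate(self, name: str) -> float | None:
        if name == "age":
            return float(self.age)
        return self.extra.get(name)
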