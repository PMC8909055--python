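"""The NTCP model registry: 16 dose-response models, CTS weights, MBS thresholds.

The registry is configuration-driven: each entry names the organ (structure)
it reads, the functional form of the dose-response curve, the dose summary it
consumes (mean dose, gEUD with a volume-effect parameter ``a``, or a
near-maximum dose), its parameters, its weight in the Comprehensive Toxicity
Score, and — for the seven models entering model-based selection (MBS) — the
standard and young-patient per-endpoint thresholds in percentage points.

A default registry ships with the package (``data/models_default.yaml``).
Its structural content (organs, endpoints, weights, thresholds, MBS flags,
evidence levels) is fixed; the dose-response parameter values are
representative defaults documented in the file, to be transcribed from the
cited model publications for clinical use.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import yaml

__all__ = [
    "NTCPModelSpec",
    "ThresholdSet",
    "ModelRegistry",
    "RegistryError",
    "load_registry",
    "default_registry_path",
]

FORMS = ("lkb_probit", "logistic_linear", "loglogistic_d50_gamma")
SUMMARY_METRICS = ("mean_dose", "geud", "d1", "d2", "dmax", "dose_at_volume")

COMPOSITE_THRESHOLD = 35.0  # percentage points, 7 MBS models x 5 points


class RegistryError(ValueError):
    """Raised when a registry configuration violates its invariants."""


@dataclass(frozen=True)
class NTCPModelSpec:
    """One registry entry (see module docstring for field semantics)."""

    model_id: str
    organ: str
    endpoint: str
    form: str
    dose_summary: dict
    parameters: dict
    cts_weight: float
    evidence_level: int = 4
    mbs_member: bool = False
    threshold_standard: float | None = None
    threshold_young: float | None = None
    reference: str = ""

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise RegistryError(f"{self.model_id}: unknown form {self.form!r}")
        metric = self.dose_summary.get("metric")
        if metric not in SUMMARY_METRICS:
            raise RegistryError(
                f"{self.model_id}: unknown dose summary metric {metric!r}"
            )
        if metric == "geud" and not self.dose_summary.get("a"):
            raise RegistryError(f"{self.model_id}: gEUD summary requires 'a'")
        if self.cts_weight < 0:
            raise RegistryError(f"{self.model_id}: negative CTS weight")
        if self.mbs_member and (
            self.threshold_standard is None or self.threshold_young is None
        ):
            raise RegistryError(
                f"{self.model_id}: MBS member must define standard and young thresholds"
            )

    def threshold(self, mode: str) -> float | None:
        if mode == "standard":
            return self.threshold_standard
        if mode == "young":
            return self.threshold_young
        raise ValueError(f"unknown threshold mode {mode!r}")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-endpoint MBS thresholds plus the composite threshold, in % points."""

    mode: Literal["standard", "young"]
    thresholds: dict[str, float]
    composite_threshold: float = COMPOSITE_THRESHOLD


class ModelRegistry:
    """An ordered, validated collection of :class:`NTCPModelSpec`."""

    def __init__(self, models: Iterable[NTCPModelSpec], source: str = "<memory>"):
        self.models: dict[str, NTCPModelSpec] = {}
        for m in models:
            if m.model_id in self.models:
                raise RegistryError(f"duplicate model id {m.model_id!r}")
            self.models[m.model_id] = m
        self.source = source
        self.validate()

    # -------------------------------------------------------------- #

    def validate(self) -> None:
        if not self.models:
            raise RegistryError("registry is empty")
        total = sum(m.cts_weight for m in self.models.values())
        if abs(total - 1.0) > 1e-9:
            raise RegistryError(
                f"CTS weights must sum to unity, got {total:.12f} ({self.source})"
            )

    # -------------------------------------------------------------- #

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models.values())

    def __getitem__(self, model_id: str) -> NTCPModelSpec:
        return self.models[model_id]

    def __contains__(self, model_id: str) -> bool:
        return model_id in self.models

    @property
    def model_ids(self) -> list[str]:
        return list(self.models)

    @property
    def mbs_ids(self) -> list[str]:
        return [m.model_id for m in self if m.mbs_member]

    def weights(self) -> dict[str, float]:
        return {m.model_id: m.cts_weight for m in self}

    def thresholds(self, mode: str = "standard") -> ThresholdSet:
        if mode not in ("standard", "young"):
            raise ValueError(f"unknown threshold mode {mode!r}")
        return ThresholdSet(
            mode=mode,
            thresholds={m.model_id: m.threshold(mode) for m in self if m.mbs_member},
        )

    def organs(self) -> set[str]:
        return {m.organ for m in self}

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_dict(self) -> list[dict]:
        out = []
        for m in self:
            d = {
                "id": m.model_id,
                "organ": m.organ,
                "endpoint": m.endpoint,
                "form": m.form,
                "dose_summary": dict(m.dose_summary),
                "parameters": m.parameters,
                "cts_weight": m.cts_weight,
                "evidence_level": m.evidence_level,
                "mbs_member": m.mbs_member,
                "reference": m.reference,
            }
            if m.mbs_member:
                d["threshold_standard"] = m.threshold_standard
                d["threshold_young"] = m.threshold_young
            out.append(d)
        return out


def _spec_from_dict(d: dict) -> NTCPModelSpec:
    try:
        return NTCPModelSpec(
            model_id=d["id"],
            organ=d["organ"],
            endpoint=d.get("endpoint", ""),
            form=d["form"],
            dose_summary=d.get("dose_summary", {"metric": "mean_dose"}),
            parameters=d.get("parameters", {}),
            cts_weight=float(d["cts_weight"]),
            evidence_level=int(d.get("evidence_level", 4)),
            mbs_member=bool(d.get("mbs_member", False)),
            threshold_standard=d.get("threshold_standard"),
            threshold_young=d.get("threshold_young"),
            reference=d.get("reference", ""),
        )
    except KeyError as exc:
        raise RegistryError(f"registry entry missing required key {exc}") from exc


def default_registry_path() -> Path:
    return Path(resources.files("ntcpselect") / "data" / "models_default.yaml")


def load_registry(path: str | Path | None = None) -> ModelRegistry:
    """Load a registry from YAML; with no path, the shipped default set."""
    p = Path(path) if path is not None else default_registry_path()
    with open(p, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw.get("models", raw)
    if not isinstance(raw, list):
        raise RegistryError(f"{p}: expected a list of model entries")
    return ModelRegistry((_spec_from_dict(d) for d in raw), source=str(p))
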