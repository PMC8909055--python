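"""NTCP evaluation: gEUD, the three dose-response forms, and plan deltas.

Three functional forms cover the model families in the default registry:

* ``lkb_probit`` — the Lyman-Kutcher-Burman probit curve
  ``NTCP = Phi((S - TD50) / (m * TD50))`` on a dose summary ``S`` (gEUD,
  mean dose, or a near-maximum dose), with ``Phi`` the standard normal CDF.
* ``logistic_linear`` — a multivariable logistic model
  ``NTCP = 1 / (1 + exp(-(b0 + sum b_i x_i)))`` whose terms are dose
  summaries of the model's organ and/or named patient covariates.
* ``loglogistic_d50_gamma`` — ``NTCP = 1 / (1 + (D50 / S)^(4 * gamma50))``.

All forms are intrinsically bounded in [0, 1]; no clipping is applied.
A model that cannot be evaluated (missing structure or covariate) raises
:class:`ModelNotEvaluable`; cohort-level helpers record ``None`` for it and
log a warning instead of silently imputing zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .dvh import StructureDVH, dose_at_volume, mean_dose
from .records import PatientCovariates, PlanRecord
from .registry import ModelRegistry, NTCPModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ModelNotEvaluable",
    "PlanNTCP",
    "geud",
    "dose_summary",
    "probability_from_resolver",
    "evaluate_model",
    "evaluate_plan",
    "delta_ntcp",
]


class ModelNotEvaluable(RuntimeError):
    """The model's organ or a required covariate is missing for this plan."""


def geud(dvh: StructureDVH, a: float) -> float:
    """Generalized equivalent uniform dose ``(sum v_i d_i^a)^(1/a)``.

    ``a = 1`` reduces to the mean dose; large ``a`` approaches the maximum
    dose (serial organs), ``a`` near 0 or negative emphasises cold spots
    (parallel organs).  For ``a < 0`` zero-dose bins are excluded and the
    power mean is taken over the irradiated fraction, with a warning.
    """
    if a == 0:
        raise ValueError("gEUD volume-effect parameter a must be nonzero")
    d = dvh.bin_centers()
    v = dvh.bin_fractions()
    total = v.sum()
    if total <= 0:
        raise ValueError(f"{dvh.structure_id}: empty DVH has no gEUD")
    v = v / total
    if a < 0:
        pos = d > 1e-6  # doses below 1e-6 Gy count as unirradiated
        if not np.any(pos & (v > 0)):
            raise ValueError(
                f"{dvh.structure_id}: gEUD undefined for a < 0 with all-zero dose"
            )
        if np.any(~pos & (v > 0)):
            logger.warning(
                "event=geud_zero_dose structure=%s a=%.3g zero-dose bins excluded",
                dvh.structure_id, a,
            )
        d, v = d[pos], v[pos]
        v = v / v.sum()
    if a == 1:
        return float(np.sum(v * d))
    with np.errstate(divide="ignore"):
        return float(np.sum(v * d**a) ** (1.0 / a))


def dose_summary(dvh: StructureDVH, spec: dict) -> float:
    """Evaluate a dose-summary specification on a structure DVH."""
    metric = spec["metric"]
    if metric == "mean_dose":
        return mean_dose(dvh)
    if metric == "geud":
        return geud(dvh, float(spec["a"]))
    if metric in ("d1", "dmax"):
        return dose_at_volume(dvh, 0.01)
    if metric == "d2":
        return dose_at_volume(dvh, 0.02)
    if metric == "dose_at_volume":
        return dose_at_volume(dvh, float(spec["volume_fraction"]))
    raise ValueError(f"unknown dose summary metric {metric!r}")


def _organ_dvh(model: NTCPModelSpec, plan: PlanRecord) -> StructureDVH:
    try:
        return plan.structures[model.organ]
    except KeyError:
        raise ModelNotEvaluable(
            f"{model.model_id}: structure {model.organ!r} missing from "
            f"{plan.modality} plan of {plan.patient_id}"
        ) from None


def probability_from_resolver(
    model: NTCPModelSpec,
    resolver,
    covariates: PatientCovariates | None = None,
    context: str = "",
) -> float:
    """Apply the model's dose-response form to resolved dose summaries.

    ``resolver`` maps a dose-summary specification dict to a scalar dose in
    Gy(RBE); this lets callers evaluate models either on full
    :class:`StructureDVH` objects or on pre-binned arrays.
    """
    if model.form == "lkb_probit":
        s = resolver(model.dose_summary)
        td50 = float(model.parameters["td50"])
        m = float(model.parameters["m"])
        return float(norm.cdf((s - td50) / (m * td50)))
    if model.form == "logistic_linear":
        lp = float(model.parameters.get("intercept", 0.0))
        for term in model.parameters.get("terms", []):
            feature = term["feature"]
            coef = float(term["coef"])
            if feature == "covariate":
                name = term["name"]
                value = covariates.covariate(name) if covariates is not None else None
                if value is None:
                    raise ModelNotEvaluable(
                        f"{model.model_id}: covariate {name!r} missing{context}"
                    )
            else:
                value = resolver({**model.dose_summary, "metric": feature,
                                  "a": term.get("a", model.dose_summary.get("a"))})
            lp += coef * float(value)
        return float(1.0 / (1.0 + np.exp(-lp)))
    if model.form == "loglogistic_d50_gamma":
        s = resolver(model.dose_summary)
        if s <= 0:
            return 0.0
        d50 = float(model.parameters["d50"])
        g = float(model.parameters["gamma50"])
        return float(1.0 / (1.0 + (d50 / s) ** (4.0 * g)))
    raise ValueError(f"unknown form {model.form!r}")


def evaluate_model(
    model: NTCPModelSpec,
    plan: PlanRecord,
    covariates: PatientCovariates | None = None,
) -> float:
    """Complication probability of one model for one plan, in [0, 1]."""
    dvh = _organ_dvh(model, plan)
    return probability_from_resolver(
        model,
        lambda spec: dose_summary(dvh, spec),
        covariates,
        context=f" for {plan.patient_id}",
    )


@dataclass
class PlanNTCP:
    """Per-model complication probabilities for one patient's plan.

    ``probabilities`` maps model id to a probability in [0, 1], or ``None``
    for a model that was not evaluable on this plan.
    """

    patient_id: str
    modality: str
    probabilities: dict[str, float | None]


def evaluate_plan(
    registry: ModelRegistry,
    plan: PlanRecord,
    covariates: PatientCovariates | None = None,
) -> PlanNTCP:
    """Evaluate every registry model on a plan; not-evaluable models warn."""
    probs: dict[str, float | None] = {}
    for model in registry:
        try:
            probs[model.model_id] = evaluate_model(model, plan, covariates)
        except ModelNotEvaluable as exc:
            logger.warning("event=model_not_evaluable detail=%s", exc)
            probs[model.model_id] = None
    return PlanNTCP(plan.patient_id, plan.modality, probs)


def delta_ntcp(photon: PlanNTCP, proton: PlanNTCP) -> dict[str, float | None]:
    """Per-model ``100 * (NTCP_photon - NTCP_proton)`` in percentage points.

    Positive values favour protons.  A model evaluable in only one of the
    two plans is excluded pairwise (``None``) with a warning.
    """
    if photon.patient_id != proton.patient_id:
        raise ValueError(
            f"paired plans belong to different patients: "
            f"{photon.patient_id!r} vs {proton.patient_id!r}"
        )
    if set(photon.probabilities) != set(proton.probabilities):
        raise ValueError("paired plans were evaluated against different registries")
    out: dict[str, float | None] = {}
    for model_id, p_x in photon.probabilities.items():
        p_p = proton.probabilities[model_id]
        if p_x is None or p_p is None:
            logger.warning(
                "event=delta_not_evaluable patient=%s model=%s",
                photon.patient_id, model_id,
            )
            out[model_id] = None
        else:
            out[model_id] = 100.0 * (p_x - p_p)
    return out
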