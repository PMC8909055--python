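"""Comprehensive Toxicity Score and model-based selection (MBS) verdicts.

The CTS is the weighted sum of all 16 per-endpoint NTCP differences (photon
minus proton, percentage points); the weights express clinical relevance and
sum to unity, so an across-the-board gain of x points yields a CTS of
exactly x.

MBS eligibility applies two rules to the seven clinically most relevant
endpoints:

* single rule — the patient qualifies if any single delta-NTCP is strictly
  larger than its per-endpoint threshold ("larger than", hence ``>``);
* composite rule — the patient qualifies if the summed delta-NTCP over the
  seven MBS models is at least the composite threshold of 35 points
  (constructed as an ideal concomitant 5-point gain on each of the 7
  models), hence ``>=``.

The boundary conventions differ between the two rules on purpose.
Negative deltas enter the composite sum as-is by default; an optional
clamp-at-zero mode is available and recorded in every result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .registry import ThresholdSet

logger = logging.getLogger(__name__)

__all__ = [
    "EligibilityResult",
    "EligibilityCounts",
    "cts_score",
    "mbs_eligibility",
    "eligible_fraction",
]


def cts_score(delta_map: dict[str, float | None], weights: dict[str, float]) -> float:
    """Weighted sum of delta-NTCP values (percentage points) over the registry.

    Weights are validated to sum to unity at registry load, not here.
    Not-evaluable deltas (``None``) are excluded pairwise with a warning;
    negative deltas enter sign-preserved.
    """
    total = 0.0
    for model_id, w in weights.items():
        delta = delta_map.get(model_id)
        if delta is None:
            logger.warning("event=cts_term_excluded model=%s", model_id)
            continue
        total += w * delta
    return total


@dataclass
class EligibilityResult:
    """Per-patient MBS verdict with the full evidence trail."""

    patient_id: str
    mode: str
    delta_map: dict[str, float | None]
    single_pass_flags: dict[str, bool]
    composite_sum: float | None
    cts: float
    eligible: bool | None
    reason: str  # single | composite | both | none | not_evaluable
    clamp_negative: bool = False
    not_evaluable_models: list[str] = field(default_factory=list)


def mbs_eligibility(
    patient_id: str,
    delta_map: dict[str, float | None],
    thresholds: ThresholdSet,
    weights: dict[str, float],
    clamp_negative: bool = False,
) -> EligibilityResult:
    """Apply the MBS rules to one patient's delta-NTCP vector.

    A missing or not-evaluable MBS delta yields an explicit not-evaluable
    verdict (``eligible=None``), never a default "ineligible".
    """
    cts = cts_score(delta_map, weights)
    missing = [m for m in thresholds.thresholds if delta_map.get(m) is None]
    if missing:
        logger.warning(
            "event=verdict_not_evaluable patient=%s missing=%s", patient_id, missing
        )
        return EligibilityResult(
            patient_id=patient_id,
            mode=thresholds.mode,
            delta_map=delta_map,
            single_pass_flags={},
            composite_sum=None,
            cts=cts,
            eligible=None,
            reason="not_evaluable",
            clamp_negative=clamp_negative,
            not_evaluable_models=missing,
        )
    flags = {
        m: delta_map[m] > thr for m, thr in thresholds.thresholds.items()
    }
    terms = (
        max(delta_map[m], 0.0) if clamp_negative else delta_map[m]
        for m in thresholds.thresholds
    )
    composite = sum(terms)
    single = any(flags.values())
    comp = composite >= thresholds.composite_threshold
    reason = {
        (True, True): "both",
        (True, False): "single",
        (False, True): "composite",
        (False, False): "none",
    }[(single, comp)]
    return EligibilityResult(
        patient_id=patient_id,
        mode=thresholds.mode,
        delta_map=delta_map,
        single_pass_flags=flags,
        composite_sum=composite,
        cts=cts,
        eligible=single or comp,
        reason=reason,
        clamp_negative=clamp_negative,
    )


@dataclass(frozen=True)
class EligibilityCounts:
    """Cohort eligibility tallies via inclusion-exclusion."""

    n: int
    single: int          # patients passing any single-endpoint rule
    composite: int       # patients passing the composite rule
    both: int            # passing both rules
    not_evaluable: int = 0

    @property
    def single_only(self) -> int:
        return self.single - self.both

    @property
    def composite_only(self) -> int:
        return self.composite - self.both

    @property
    def union(self) -> int:
        return self.single + self.composite - self.both

    @property
    def fraction(self) -> float:
        return self.union / self.n


def eligible_fraction(results: list[EligibilityResult]) -> EligibilityCounts:
    """Union count |single OR composite| over a non-empty cohort."""
    if not results:
        raise ValueError("empty cohort")
    single = sum(1 for r in results if r.reason in ("single", "both"))
    comp = sum(1 for r in results if r.reason in ("composite", "both"))
    both = sum(1 for r in results if r.reason == "both")
    nne = sum(1 for r in results if r.reason == "not_evaluable")
    return EligibilityCounts(
        n=len(results), single=single, composite=comp, both=both, not_evaluable=nne
    )
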