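"""Dose-volume histograms and dosimetric plan-quality metrics.

A :class:`StructureDVH` stores one structure's dose distribution either as a
differential histogram (bin edges plus per-bin volume fractions) or as a
cumulative curve (dose points plus the fraction of the structure receiving at
least that dose).  The cumulative form is the canonical internal
representation; every metric auto-converts as needed.

Conventions
-----------
* Doses are in Gy(RBE), volumes in cm3, volume fractions in [0, 1].
* Dx% is the minimum dose received by the hottest x% of the volume, obtained
  by linear interpolation on the cumulative curve; on a flat segment the
  highest qualifying dose is returned (the dominant TPS convention).
* The conformity index CI is the fraction of the PTV receiving at least 95%
  of its prescription dose; the homogeneity index HI is (D2% - D98%) / D50%.
* Integral dose is the mean dose to the CT-scanned body times the body
  volume, in Gy(RBE) cm3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DVHValidationError",
    "StructureDVH",
    "DoseMetricSet",
    "dose_at_volume",
    "volume_at_dose",
    "mean_dose",
    "conformity_index",
    "homogeneity_index",
    "integral_dose",
    "compute_metrics",
]


class DVHValidationError(ValueError):
    """Raised when a DVH violates its structural invariants."""


Representation = Literal["differential", "cumulative"]


@dataclass(frozen=True)
class StructureDVH:
    """One structure's dose-volume distribution.

    Parameters
    ----------
    structure_id:
        Text label of the structure (e.g. ``"parotid"``).
    total_volume_cc:
        Absolute structure volume in cm3; must be positive.
    dose_gy:
        For the differential representation, the ``n + 1`` strictly
        increasing bin edges; for the cumulative representation, the ``n``
        strictly increasing dose points.
    volume:
        For the differential representation, the ``n`` non-negative bin
        volume fractions (summing to <= 1); for the cumulative
        representation, the non-increasing fraction of the structure
        receiving at least each dose.
    representation:
        ``"differential"`` or ``"cumulative"``.
    """

    structure_id: str
    total_volume_cc: float
    dose_gy: np.ndarray
    volume: np.ndarray
    representation: Representation = "cumulative"

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_gy, dtype=float)
        vol = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "dose_gy", dose)
        object.__setattr__(self, "volume", vol)
        if self.total_volume_cc <= 0:
            raise DVHValidationError(
                f"{self.structure_id}: total volume must be positive, "
                f"got {self.total_volume_cc}"
            )
        if dose.ndim != 1 or vol.ndim != 1:
            raise DVHValidationError(f"{self.structure_id}: arrays must be 1-D")
        if dose.size == 0 or vol.size == 0:
            raise DVHValidationError(f"{self.structure_id}: empty DVH")
        if np.any(dose < 0):
            raise DVHValidationError(f"{self.structure_id}: negative dose values")
        if np.any(np.diff(dose) <= 0):
            raise DVHValidationError(
                f"{self.structure_id}: dose values must be strictly increasing"
            )
        if np.any(vol < -1e-12):
            raise DVHValidationError(f"{self.structure_id}: negative volume fractions")
        if self.representation == "differential":
            if vol.size != dose.size - 1:
                raise DVHValidationError(
                    f"{self.structure_id}: differential DVH needs len(edges) == "
                    f"len(fractions) + 1"
                )
            if vol.sum() > 1 + 1e-9:
                raise DVHValidationError(
                    f"{self.structure_id}: differential fractions sum to "
                    f"{vol.sum():.6f} > 1"
                )
        elif self.representation == "cumulative":
            if vol.size != dose.size:
                raise DVHValidationError(
                    f"{self.structure_id}: cumulative DVH needs len(dose) == len(volume)"
                )
            if np.any(np.diff(vol) > 1e-12):
                raise DVHValidationError(
                    f"{self.structure_id}: cumulative curve must be non-increasing"
                )
            if vol[0] > 1 + 1e-9:
                raise DVHValidationError(
                    f"{self.structure_id}: cumulative fraction exceeds 1"
                )
        else:
            raise DVHValidationError(
                f"{self.structure_id}: unknown representation {self.representation!r}"
            )

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_differential(
        cls,
        structure_id: str,
        total_volume_cc: float,
        bin_edges: Iterable[float],
        bin_fractions: Iterable[float],
    ) -> "StructureDVH":
        return cls(structure_id, total_volume_cc, np.asarray(bin_edges, float),
                   np.asarray(bin_fractions, float), "differential")

    @classmethod
    def from_cumulative(
        cls,
        structure_id: str,
        total_volume_cc: float,
        dose_gy: Iterable[float],
        cum_fractions: Iterable[float],
    ) -> "StructureDVH":
        dose = np.asarray(dose_gy, float)
        cum = np.asarray(cum_fractions, float)
        if dose.size and dose[0] > 0:
            # canonical curves are anchored at dose 0
            dose = np.concatenate([[0.0], dose])
            cum = np.concatenate([[cum[0]], cum])
        return cls(structure_id, total_volume_cc, dose, cum, "cumulative")

    @classmethod
    def from_voxels(
        cls,
        structure_id: str,
        total_volume_cc: float,
        voxel_doses: Iterable[float],
        bin_width: float = 0.1,
    ) -> "StructureDVH":
        """Bin equal-volume voxel doses into a differential DVH."""
        doses = np.asarray(list(voxel_doses), float)
        if doses.size == 0:
            raise DVHValidationError(f"{structure_id}: no voxels")
        hi = max(doses.max() + bin_width, bin_width)
        edges = np.arange(0.0, hi + bin_width, bin_width)
        counts, _ = np.histogram(doses, bins=edges)
        return cls.from_differential(
            structure_id, total_volume_cc, edges, counts / doses.size
        )

    @classmethod
    def uniform(
        cls,
        structure_id: str,
        total_volume_cc: float,
        dose: float,
        bin_width: float = 0.01,
    ) -> "StructureDVH":
        """Whole structure at a single dose, as one narrow bin centred on it."""
        lo = max(dose - bin_width / 2, 0.0)
        return cls.from_differential(
            structure_id, total_volume_cc, [lo, lo + bin_width], [1.0]
        )

    # ------------------------------------------------------------------ #
    # representation conversion

    def to_cumulative(self) -> "StructureDVH":
        """Reverse partial sums of the differential bins, evaluated at the edges."""
        if self.representation == "cumulative":
            logger.info("event=dvh_noop structure=%s already cumulative", self.structure_id)
            return self
        cum = np.concatenate([np.cumsum(self.volume[::-1])[::-1], [0.0]])
        return StructureDVH(
            self.structure_id, self.total_volume_cc, self.dose_gy, cum, "cumulative"
        )

    def to_differential(self) -> "StructureDVH":
        if self.representation == "differential":
            return self
        frac = -np.diff(self.volume)
        frac = np.clip(frac, 0.0, None)
        residual = float(self.volume[-1])
        dose = self.dose_gy
        if residual > 1e-12:
            # mass at or above the last dose point: narrow terminal bin
            logger.warning(
                "event=dvh_residual structure=%s residual=%.3e assigned to last dose",
                self.structure_id, residual,
            )
            dose = np.concatenate([dose, [dose[-1] + 1e-6]])
            frac = np.concatenate([frac, [residual]])
        return StructureDVH(
            self.structure_id, self.total_volume_cc, dose, frac, "differential"
        )

    # ------------------------------------------------------------------ #
    # convenience

    @property
    def coverage(self) -> float:
        """Fraction of the structure covered by the dose grid (1.0 when full)."""
        if self.representation == "differential":
            return float(self.volume.sum())
        return float(self.volume[0])

    def bin_centers(self) -> np.ndarray:
        d = self.to_differential()
        return 0.5 * (d.dose_gy[:-1] + d.dose_gy[1:])

    def bin_fractions(self) -> np.ndarray:
        return self.to_differential().volume

    def scaled(self, factor: float) -> "StructureDVH":
        """Return the DVH with every dose multiplied by ``factor`` > 0."""
        if factor <= 0:
            raise DVHValidationError("dose scaling factor must be positive")
        return replace(self, dose_gy=self.dose_gy * factor)


# ---------------------------------------------------------------------- #
# metrics


def _cumulative(dvh: StructureDVH) -> StructureDVH:
    c = dvh.to_cumulative()
    if c.coverage < 1 - 1e-6:
        logger.warning(
            "event=partial_coverage structure=%s coverage=%.4f metrics refer to "
            "the covered fraction", c.structure_id, c.coverage,
        )
    return c


def dose_at_volume(dvh: StructureDVH, volume_fraction: float) -> float:
    """Dx: minimum dose received by the hottest ``volume_fraction`` of the volume.

    Linear interpolation between cumulative points; on flat segments the
    highest qualifying dose is returned.
    """
    if not 0 < volume_fraction <= 1:
        raise ValueError(f"volume_fraction must be in (0, 1], got {volume_fraction}")
    c = _cumulative(dvh)
    dose, cum = c.dose_gy, c.volume
    rev_c = cum[::-1]  # non-decreasing
    rev_d = dose[::-1]
    eps = 1e-9  # tolerance so binning round-off cannot hide a flat segment
    if volume_fraction > rev_c[-1] + eps:
        # more volume requested than is covered by the grid: only dose 0 qualifies
        return 0.0
    i = int(np.searchsorted(rev_c, volume_fraction - eps, side="left"))
    if abs(rev_c[i] - volume_fraction) <= eps:
        return float(rev_d[i])
    if i == 0:
        # curve never reaches this low a fraction: mass sits at/above the top point
        return float(rev_d[0])
    # rev_c[i-1] < volume_fraction < rev_c[i]
    lo_c, hi_c = rev_c[i - 1], rev_c[i]
    lo_d, hi_d = rev_d[i - 1], rev_d[i]
    t = (volume_fraction - lo_c) / (hi_c - lo_c)
    return float(lo_d + t * (hi_d - lo_d))


def volume_at_dose(dvh: StructureDVH, dose: float) -> float:
    """Fraction of the structure receiving at least ``dose`` Gy(RBE)."""
    c = _cumulative(dvh)
    if dose <= c.dose_gy[0]:
        return float(c.volume[0])
    if dose >= c.dose_gy[-1]:
        return float(c.volume[-1])
    return float(np.interp(dose, c.dose_gy, c.volume))


def mean_dose(dvh: StructureDVH) -> float:
    """Volume-weighted average dose, from differential bin midpoints."""
    d = dvh.to_differential()
    total = d.volume.sum()
    if total <= 0:
        raise DVHValidationError(f"{dvh.structure_id}: zero-coverage DVH has no mean")
    centers = 0.5 * (d.dose_gy[:-1] + d.dose_gy[1:])
    return float(np.sum(d.volume * centers) / total)


def conformity_index(ptv_dvh: StructureDVH, prescription: float) -> float:
    """CI: fraction of the PTV receiving >= 95% of its prescription dose."""
    if prescription <= 0:
        raise ValueError("prescription dose must be positive")
    return volume_at_dose(ptv_dvh, 0.95 * prescription)


def homogeneity_index(dvh: StructureDVH) -> float:
    """HI = (D2% - D98%) / D50%; undefined when D50% is zero."""
    d50 = dose_at_volume(dvh, 0.50)
    if d50 <= 0:
        raise DVHValidationError(
            f"{dvh.structure_id}: homogeneity index undefined for D50 = 0"
        )
    return (dose_at_volume(dvh, 0.02) - dose_at_volume(dvh, 0.98)) / d50


def integral_dose(body_dvh: StructureDVH) -> float:
    """Mean body dose times body volume, Gy(RBE) cm3."""
    return mean_dose(body_dvh) * body_dvh.total_volume_cc


@dataclass(frozen=True)
class DoseMetricSet:
    """The dose quantifiers reported for a structure under one plan."""

    D99: float
    D98: float
    D95: float
    D50: float
    D2: float
    D1: float
    Davg: float
    V95_fraction: float = float("nan")
    V100_fraction: float = float("nan")
    CI: float = float("nan")
    HI: float = float("nan")
    integral_dose: float = field(default=float("nan"))


def compute_metrics(
    dvh: StructureDVH, prescription: float | None = None
) -> DoseMetricSet:
    """All dose quantifiers for one structure.

    ``prescription`` (the structure's own prescription level for multi-level
    plans) enables the coverage metrics V95%, V100% and CI; without it those
    fields are NaN.
    """
    d = {x: dose_at_volume(dvh, x / 100) for x in (99, 98, 95, 50, 2, 1)}
    davg = mean_dose(dvh)
    kwargs = dict(
        D99=d[99], D98=d[98], D95=d[95], D50=d[50], D2=d[2], D1=d[1], Davg=davg,
        integral_dose=davg * dvh.total_volume_cc,
    )
    if prescription is not None:
        kwargs["V95_fraction"] = volume_at_dose(dvh, 0.95 * prescription)
        kwargs["V100_fraction"] = volume_at_dose(dvh, prescription)
        kwargs["CI"] = conformity_index(dvh, prescription)
    try:
        kwargs["HI"] = homogeneity_index(dvh)
    except DVHValidationError:
        pass
    return DoseMetricSet(**kwargs)
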