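"""Seeded synthetic paired photon/proton cohorts.

The generator emulates the statistical structure the selection analysis
assumes, so every downstream stage is testable without clinical data:

* clinical covariates drawn from the study cohort's categorical mix
  (T stage 40/14/30/16%, N stage 16/28/30/26%, treatment 8/54/38%) with
  prescription schemes 69.96 / 59.4 / 56.1 Gy(RBE) in 33 fractions
  (two-level 56.1: 24%, two-level 59.4: 20%, three-level: 56%);
* per structure, a photon cumulative DVH from a two-parameter logistic
  (sigmoid) family, truncated and renormalized on [0, dmax] — chosen for
  analytic invertibility of mean/gEUD targets; OARs close to the target
  (brain, optic pathways, cochlea, superior PCM, ...) receive a T-stage-
  dependent upward dose shift;
* the proton plan applies a structure-specific multiplicative sparing
  factor, predominantly in the low-to-middle dose range for near-target
  structures (near-maximum doses preserved), and across the whole dose
  range for structures a few centimetres from the target (spinal cord,
  brain, ...), where near-maximum doses also drop;
* both plans' targets are drawn from the same family around the
  prescription dose and meet the V95 >= 0.95 coverage goal by construction,
  so target metrics are equivalent between modalities.

One global seed governs all sampling; each patient draws from a
deterministically derived substream, so a cohort can be extended without
reshuffling earlier patients.

:func:`plant_effect` inverts the generator: it tunes a structure's sparing
factor by bisection so the expected fraction of patients whose delta-NTCP
exceeds a model's MBS threshold matches a requested target, enabling
parameter-recovery experiments with known ground truth.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .dvh import StructureDVH
from .ntcp import ModelNotEvaluable, probability_from_resolver
from .records import PatientCovariates, PlanRecord, PrescriptionLevel, TREATMENTS
from .registry import ModelRegistry, NTCPModelSpec, load_registry

logger = logging.getLogger(__name__)

__all__ = [
    "StructureSim",
    "GeneratorConfig",
    "GeneratorConfigError",
    "default_config",
    "generate_cohort",
    "plant_effect",
]

PRESCRIPTION_HD = 69.96
PRESCRIPTION_ID = 59.4
PRESCRIPTION_LD_LOW = 56.1
SCHEMES = ("two_56", "two_59", "three")


class GeneratorConfigError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class StructureSim:
    """Sampling parameters for one structure's photon/proton DVH pair.

    ``d50_gy``/``k_gy`` locate and spread the sigmoid cumulative curve;
    ``t_shift_gy`` is the upward dose shift per T stage above T1 (near-target
    structures only); ``sparing_mean``/``sparing_sd`` parameterize the
    per-patient proton sparing factor in (0, 1]; ``high_dose_preserved``
    selects the near-target dose transform that leaves near-maximum doses
    unchanged.  Targets (``target_level`` set) ignore the sparing machinery.
    """

    name: str
    d50_gy: float
    k_gy: float
    volume_cc: float
    volume_sd: float = 0.0
    d50_sd: float = 3.0
    k_sd: float = 0.8
    t_shift_gy: float = 0.0
    sparing_mean: float = 1.0
    sparing_sd: float = 0.0
    high_dose_preserved: bool = True
    target_level: str | None = None  # "hd" | "id" | "ld"

    def __post_init__(self) -> None:
        if not 0 < self.sparing_mean <= 1:
            raise GeneratorConfigError(
                f"{self.name}: sparing factor must be in (0, 1], "
                f"got {self.sparing_mean}"
            )
        if self.k_gy <= 0 or self.d50_gy < 0:
            raise GeneratorConfigError(f"{self.name}: invalid sigmoid parameters")


def _default_structures() -> dict[str, StructureSim]:
    # Sparing-factor means for the structures feeding MBS endpoints were set
    # by inverting the generator (plant_effect) against the cohort-level
    # per-endpoint passing rates the analysis is designed around (xerostomia
    # 24%, brain necrosis 8%, mucositis 6%, trismus 6%, dysphagia 2%);
    # cochlea and thyroid were set to reproduce mean delta-NTCP levels of
    # ~8.6 and ~9.3 points for tinnitus and hypothyroidism.
    specs = [
        # OARs: name, d50, k, vol, vol_sd, d50_sd, k_sd, t_shift, f_mean, f_sd, hi_preserved
        ("parotid",        25.0, 7.0,   28.0,   6.0, 4.0, 0.8, 0.0, 0.740, 0.08, True),
        ("pcm_superior",   58.0, 4.0,   12.0,   3.0, 3.0, 0.5, 1.0, 0.925, 0.03, True),
        ("oral_cavity",    35.0, 7.0,  120.0,  25.0, 4.0, 0.8, 0.0, 0.868, 0.06, True),
        ("brain",           6.0, 9.0, 1400.0, 150.0, 2.0, 1.0, 2.5, 0.972, 0.06, False),
        ("temporal_lobe",  35.0, 12.0,  90.0,  15.0, 4.0, 1.0, 2.0, 0.90, 0.04, True),
        ("optic_pathways", 21.0, 5.5,    8.0,   2.0, 2.5, 0.8, 1.0, 0.90, 0.04, True),
        ("glottic_larynx", 38.0, 8.0,   25.0,   5.0, 4.0, 0.8, 0.0, 0.72, 0.07, False),
        ("cochlea",        38.0, 7.0,    0.6,   0.1, 4.0, 0.8, 2.0, 0.886, 0.05, True),
        ("tmj",            32.0, 8.0,   18.0,   4.0, 5.0, 0.8, 0.0, 0.741, 0.06, True),
        ("thyroid",        44.0, 6.0,   20.0,   5.0, 4.0, 0.8, 0.0, 0.868, 0.06, False),
        ("spinal_cord",    30.0, 6.0,   45.0,   8.0, 3.0, 0.8, 0.0, 0.75, 0.06, False),
        ("brainstem",      40.0, 8.0,   28.0,   5.0, 3.0, 0.8, 1.5, 0.80, 0.06, True),
        ("esophagus",      18.0, 8.0,   35.0,   8.0, 3.0, 0.8, 0.0, 0.65, 0.08, False),
        ("mandible",       45.0, 10.0,  65.0,  12.0, 4.0, 1.0, 0.0, 0.85, 0.05, True),
        ("body",            6.0, 8.0, 9500.0, 1200.0, 1.5, 1.0, 0.0, 0.55, 0.05, False),
    ]
    out = {
        name: StructureSim(
            name=name, d50_gy=d50, k_gy=k, volume_cc=vol, volume_sd=vol_sd,
            d50_sd=d50_sd, k_sd=k_sd, t_shift_gy=shift,
            sparing_mean=f_mean, sparing_sd=f_sd, high_dose_preserved=hi,
        )
        for name, d50, k, vol, vol_sd, d50_sd, k_sd, shift, f_mean, f_sd, hi in specs
    }
    # targets: narrow sigmoid just above the prescription level (set at sampling
    # time from the patient's scheme); volumes from the study cohort means
    out["ptv_hd"] = StructureSim("ptv_hd", PRESCRIPTION_HD * 1.004, 0.7, 239.5, 111.2,
                                 d50_sd=0.15, k_sd=0.05, target_level="hd")
    out["ptv_id"] = StructureSim("ptv_id", PRESCRIPTION_ID * 1.004, 0.7, 447.1, 200.5,
                                 d50_sd=0.15, k_sd=0.05, target_level="id")
    out["ptv_ld"] = StructureSim("ptv_ld", PRESCRIPTION_LD_LOW * 1.004, 0.7, 612.2, 129.9,
                                 d50_sd=0.15, k_sd=0.05, target_level="ld")
    return out


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    n_patients: int = 50
    seed: int = 0
    t_probs: tuple = (0.40, 0.14, 0.30, 0.16)       # T1..T4
    n_probs: tuple = (0.16, 0.28, 0.30, 0.26)       # N0..N3
    treatment_probs: tuple = (0.08, 0.54, 0.38)     # RT alone / RT-CHT / iCHT+RT-CHT
    scheme_probs: tuple = (0.24, 0.20, 0.56)        # two_56 / two_59 / three
    structures: dict[str, StructureSim] = field(default_factory=_default_structures)
    bin_width_gy: float = 0.1
    dose_cap_gy: float = 80.0
    coverage_goal: float = 0.95
    age_mean: float = 51.0
    age_sd: float = 11.0
    age_range: tuple = (24, 72)

    def __post_init__(self) -> None:
        for name, probs in (("t_probs", self.t_probs), ("n_probs", self.n_probs),
                            ("treatment_probs", self.treatment_probs),
                            ("scheme_probs", self.scheme_probs)):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise GeneratorConfigError(f"{name} must sum to 1, got {sum(probs)}")
        self._validate_coverage()

    def _validate_coverage(self) -> None:
        """Nominal target curves must meet the coverage goal analytically."""
        rx = {"hd": PRESCRIPTION_HD, "id": PRESCRIPTION_ID, "ld": PRESCRIPTION_LD_LOW}
        for s in self.structures.values():
            if s.target_level is None:
                continue
            v95 = _sigmoid_cum(
                np.array([0.95 * rx[s.target_level]]), s.d50_gy, s.k_gy,
                _dmax(s.d50_gy, s.k_gy, self.dose_cap_gy),
            )[0]
            if v95 < self.coverage_goal:
                raise GeneratorConfigError(
                    f"{s.name}: nominal V95 = {v95:.3f} cannot meet the coverage "
                    f"goal {self.coverage_goal} with this DVH family"
                )


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


# ---------------------------------------------------------------------- #
# DVH family


def _dmax(d50: float, k: float, cap: float) -> float:
    return float(min(d50 + 10.0 * k, cap))


def _sigmoid_cum(d: np.ndarray, d50: float, k: float, dmax: float) -> np.ndarray:
    """Truncated, renormalized logistic cumulative DVH: 1 at dose 0, 0 at dmax."""
    s = 1.0 / (1.0 + np.exp((d - d50) / k))
    s0 = 1.0 / (1.0 + np.exp(-d50 / k))
    smax = 1.0 / (1.0 + np.exp((dmax - d50) / k))
    return np.clip((s - smax) / (s0 - smax), 0.0, 1.0)


def _proton_dose_map(d: np.ndarray, f: float, dref: float,
                     high_dose_preserved: bool) -> np.ndarray:
    """Map photon dose levels to proton dose levels under sparing factor f.

    Near-target structures keep near-maximum doses (the map pins d = dref);
    distant structures are scaled across the whole range.
    """
    if not high_dose_preserved or dref <= 0:
        return f * d
    return f * d + (1.0 - f) * d**3 / dref**2


def _overall_stage(t: int, n: int) -> str:
    if n == 3:
        return "IVB"
    if t == 4:
        return "IVA"
    if t == 3 or n == 2:
        return "III"
    if t == 1 and n == 0:
        return "I"
    return "II"


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def _sample_covariates(config: GeneratorConfig, index: int,
                       rng: np.random.Generator) -> tuple[PatientCovariates, str]:
    t = int(rng.choice(4, p=config.t_probs)) + 1
    n = int(rng.choice(4, p=config.n_probs))
    treatment = TREATMENTS[int(rng.choice(3, p=config.treatment_probs))]
    scheme = SCHEMES[int(rng.choice(3, p=config.scheme_probs))]
    lo, hi = config.age_range
    age = int(round(float(np.clip(rng.normal(config.age_mean, config.age_sd), lo, hi))))
    cov = PatientCovariates(
        patient_id=f"P{index + 1:03d}",
        age=age,
        t_stage=t,
        n_stage=n,
        overall_stage=_overall_stage(t, n),
        treatment=treatment,
        extra={"chemo": 0.0 if treatment == "RT alone" else 1.0},
    )
    return cov, scheme


def _prescriptions(scheme: str) -> list[PrescriptionLevel]:
    levels = [PrescriptionLevel("ptv_hd", PRESCRIPTION_HD)]
    if scheme == "two_56":
        levels.append(PrescriptionLevel("ptv_ld", PRESCRIPTION_LD_LOW))
    elif scheme == "two_59":
        levels.append(PrescriptionLevel("ptv_ld", PRESCRIPTION_ID))
    else:
        levels.append(PrescriptionLevel("ptv_id", PRESCRIPTION_ID))
        levels.append(PrescriptionLevel("ptv_ld", PRESCRIPTION_LD_LOW))
    return levels


def _sample_structure_pair(
    s: StructureSim,
    config: GeneratorConfig,
    t_stage: int,
    rng: np.random.Generator,
    rx: float | None = None,
    sparing_override: float | None = None,
) -> tuple[StructureDVH, StructureDVH]:
    """Draw one structure's (photon, proton) cumulative DVH pair."""
    volume = float(max(1.0, rng.normal(s.volume_cc, s.volume_sd)))
    if s.target_level is not None:
        # independent small jitters per modality; coverage equivalent by design
        pair = []
        d50_nom = (rx * 1.004) if rx is not None else s.d50_gy
        for _ in range(2):
            d50 = d50_nom + rng.normal(0.0, s.d50_sd)
            k = max(0.1, s.k_gy + rng.normal(0.0, s.k_sd))
            dmax = _dmax(d50, k, config.dose_cap_gy)
            grid = np.arange(0.0, dmax + config.bin_width_gy, config.bin_width_gy)
            pair.append(StructureDVH.from_cumulative(
                s.name, volume, grid, _sigmoid_cum(grid, d50, k, dmax)))
        return pair[0], pair[1]
    d50 = s.d50_gy + s.t_shift_gy * (t_stage - 1) + rng.normal(0.0, s.d50_sd)
    d50 = max(0.5, d50)
    k = max(0.3, s.k_gy + rng.normal(0.0, s.k_sd))
    dmax = _dmax(d50, k, config.dose_cap_gy)
    grid = np.arange(0.0, dmax + config.bin_width_gy, config.bin_width_gy)
    cum = _sigmoid_cum(grid, d50, k, dmax)
    f_mean = s.sparing_mean if sparing_override is None else sparing_override
    f = float(np.clip(rng.normal(f_mean, s.sparing_sd), 0.05, 1.0))
    photon = StructureDVH.from_cumulative(s.name, volume, grid, cum)
    if f >= 1.0:
        proton = StructureDVH.from_cumulative(s.name, volume, grid, cum)
    else:
        pd_ = _proton_dose_map(grid, f, dmax, s.high_dose_preserved)
        proton = StructureDVH.from_cumulative(s.name, volume, pd_, cum)
    return photon, proton


def generate_cohort(
    config: GeneratorConfig | None = None,
    structures: list[str] | None = None,
) -> tuple[list[PatientCovariates], list[tuple[PlanRecord, PlanRecord]]]:
    """Generate a paired photon/proton cohort.

    ``structures`` optionally restricts generation to a subset of structure
    names (useful for single-endpoint calibration studies).  Returns the
    covariate list and, per patient, the (photon, proton) plan pair.
    """
    config = config or GeneratorConfig()
    wanted = list(config.structures) if structures is None else list(structures)
    covariates: list[PatientCovariates] = []
    pairs: list[tuple[PlanRecord, PlanRecord]] = []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        cov, scheme = _sample_covariates(config, i, rng)
        rx_by_target = {p.target_id: p.dose_gy for p in _prescriptions(scheme)}
        photon_structs: dict[str, StructureDVH] = {}
        proton_structs: dict[str, StructureDVH] = {}
        for name in wanted:
            s = config.structures[name]
            if s.target_level is not None and name not in rx_by_target:
                continue  # e.g. no PTV-ID in two-level schemes
            ph, pr = _sample_structure_pair(
                s, config, cov.t_stage, rng, rx=rx_by_target.get(name)
            )
            photon_structs[name] = ph
            proton_structs[name] = pr
        prescriptions = _prescriptions(scheme)
        pairs.append((
            PlanRecord(cov.patient_id, "photon", prescriptions, photon_structs),
            PlanRecord(cov.patient_id, "proton", prescriptions, proton_structs),
        ))
        covariates.append(cov)
    return covariates, pairs


# ---------------------------------------------------------------------- #
# effect planting (generator inversion)


def _probe_summaries(spec: dict, centers: np.ndarray, fracs: np.ndarray,
                     cum_dose: np.ndarray, cum_frac: np.ndarray):
    """Dose-summary resolver over pre-binned arrays (photon side)."""
    metric = spec["metric"]
    if metric == "mean_dose":
        return float(np.sum(fracs * centers))
    if metric == "geud":
        a = float(spec["a"])
        return float(np.sum(fracs * centers**a) ** (1.0 / a))
    if metric in ("d1", "dmax", "d2", "dose_at_volume"):
        vf = {"d1": 0.01, "dmax": 0.01, "d2": 0.02}.get(metric) or float(
            spec["volume_fraction"])
        rev_c, rev_d = cum_frac[::-1], cum_dose[::-1]
        return float(np.interp(vf, rev_c, rev_d))
    raise ValueError(f"unknown dose summary metric {metric!r}")


def _pass_fraction(
    model: NTCPModelSpec,
    struct: StructureSim,
    config: GeneratorConfig,
    threshold: float,
    f_mean: float,
    probe: list,
) -> float:
    """Fraction of probe patients with delta-NTCP above the MBS threshold."""
    n_pass = 0
    for cov, grid, cum, centers, fracs, dmax, z in probe:
        photon_resolver = lambda spec: _probe_summaries(spec, centers, fracs, grid, cum)
        p_x = probability_from_resolver(model, photon_resolver, cov)
        f = float(np.clip(f_mean + struct.sparing_sd * z, 0.05, 1.0))
        pd_ = _proton_dose_map(grid, f, dmax, struct.high_dose_preserved)
        pc = _proton_dose_map(centers, f, dmax, struct.high_dose_preserved)
        proton_resolver = lambda spec: _probe_summaries(spec, pc, fracs, pd_, cum)
        p_p = probability_from_resolver(model, proton_resolver, cov)
        if 100.0 * (p_x - p_p) > threshold:
            n_pass += 1
    return n_pass / len(probe)


def _make_probe(struct: StructureSim, config: GeneratorConfig, n_probe: int):
    """Pre-draw probe patients once so bisection uses common random numbers."""
    probe = []
    for i in range(n_probe):
        rng = _patient_rng(config.seed + 10_000_019, i)
        cov, _ = _sample_covariates(config, i, rng)
        d50 = max(0.5, struct.d50_gy + struct.t_shift_gy * (cov.t_stage - 1)
                  + rng.normal(0.0, struct.d50_sd))
        k = max(0.3, struct.k_gy + rng.normal(0.0, struct.k_sd))
        dmax = _dmax(d50, k, config.dose_cap_gy)
        grid = np.arange(0.0, dmax + config.bin_width_gy, config.bin_width_gy)
        cum = _sigmoid_cum(grid, d50, k, dmax)
        fracs = np.clip(-np.diff(cum), 0.0, None)
        total = fracs.sum()
        fracs = fracs / total if total > 0 else fracs
        centers = 0.5 * (grid[:-1] + grid[1:])
        z = float(rng.normal())
        probe.append((cov, grid, cum, centers, fracs, dmax, z))
    return probe


def plant_effect(
    config: GeneratorConfig,
    targets: dict[str, float],
    registry: ModelRegistry | None = None,
    mode: str = "standard",
    n_probe: int = 4000,
) -> GeneratorConfig:
    """Tune sparing factors so expected MBS pass fractions match ``targets``.

    For each ``model_id -> desired pass fraction`` the structure the model
    reads gets its mean sparing factor set by bisection on the dose-summary
    scale, using a fixed probe population (common random numbers) so the
    pass-fraction response is monotone in the factor.  A target of 0 maps to
    a sparing factor of 1 (identical plans pass nowhere).
    """
    registry = registry or load_registry()
    thresholds = registry.thresholds(mode).thresholds
    new_structures = dict(config.structures)
    for model_id, target in targets.items():
        if not 0 <= target <= 1:
            raise ValueError(f"{model_id}: target pass fraction must be in [0, 1]")
        model = registry[model_id]
        if model_id not in thresholds:
            raise ValueError(f"{model_id} is not an MBS member; no threshold to plant")
        struct = new_structures[model.organ]
        if target == 0:
            new_structures[model.organ] = replace(struct, sparing_mean=1.0)
            continue
        probe = _make_probe(struct, config, n_probe)
        # monotonicity guard: the dose response must increase with dose
        cov0, grid, cum, centers, fracs, dmax, _ = probe[0]
        res = lambda scale: (
            lambda spec: _probe_summaries(spec, centers * scale, fracs,
                                          grid * scale, cum))
        p_hi = probability_from_resolver(model, res(1.0), cov0)
        p_lo = probability_from_resolver(model, res(0.5), cov0)
        if p_lo > p_hi + 1e-12:
            raise GeneratorConfigError(
                f"{model_id}: NTCP is not monotone in dose; cannot plant an effect"
            )
        thr = thresholds[model_id]
        f_lo, f_hi = 0.05, 1.0
        g_lo = _pass_fraction(model, struct, config, thr, f_lo, probe)
        if g_lo < target:
            raise GeneratorConfigError(
                f"{model_id}: target pass fraction {target} unreachable; "
                f"maximum attainable ~{g_lo:.3f}"
            )
        for _ in range(25):
            f_mid = 0.5 * (f_lo + f_hi)
            g_mid = _pass_fraction(model, struct, config, thr, f_mid, probe)
            if g_mid >= target:
                f_lo = f_mid
            else:
                f_hi = f_mid
        planted = 0.5 * (f_lo + f_hi)
        logger.info("event=plant_effect model=%s organ=%s sparing=%.4f target=%.3f",
                    model_id, model.organ, planted, target)
        new_structures[model.organ] = replace(struct, sparing_mean=planted)
    new_config = copy.copy(config)
    new_config.structures = new_structures
    return new_config
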