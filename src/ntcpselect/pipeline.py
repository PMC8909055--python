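"""End-to-end orchestration: simulate -> evaluate -> select -> report.

Each stage writes into an output directory together with a run manifest
(config hash, registry hash, seed, threshold mode, input digests) so that
deterministic stages re-run byte-identically from identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .io import (read_covariates_csv, read_dvh_csv, write_covariates_csv,
                 write_dvh_csv)
from .ntcp import delta_ntcp, evaluate_plan
from .records import PatientCovariates, PlanRecord
from .registry import ModelRegistry, load_registry
from .selection import EligibilityResult, eligible_fraction, mbs_eligibility
from .simulate import GeneratorConfig, generate_cohort
from .stats import (build_cohort_table, compare_groups_cts, paired_ntcp_tests,
                    passing_rate_table, round_half_up)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "simulate_to_dir", "select_cohort", "run_selection",
           "run_evaluation", "write_report"]


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance block embedded in every output directory."""

    stage: str
    seed: int | None = None
    threshold_mode: str | None = None
    clamp_negative: bool | None = None
    registry_hash: str | None = None
    config_hash: str | None = None
    input_digests: dict[str, str] = field(default_factory=dict)
    package_version: str = __version__
    created_utc: str = ""

    def write(self, out_dir: Path) -> Path:
        self.created_utc = datetime.now(timezone.utc).isoformat(timespec="seconds")
        path = Path(out_dir) / "manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    @property
    def hash(self) -> str:
        d = asdict(self)
        d.pop("created_utc", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def simulate_to_dir(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Generate a cohort and write dvh.csv + covariates.csv + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    covs, pairs = generate_cohort(config)
    plans = [p for pair in pairs for p in pair]
    rx = {pair[0].patient_id: pair[0].prescription_levels for pair in pairs}
    write_dvh_csv(plans, out / "dvh.csv")
    write_covariates_csv(covs, out / "covariates.csv", prescriptions=rx)
    cfg_hash = hashlib.sha256(
        json.dumps({"n": config.n_patients, "seed": config.seed},
                   sort_keys=True).encode()).hexdigest()[:16]
    RunManifest(stage="simulate", seed=config.seed, config_hash=cfg_hash).write(out)
    logger.info("event=simulated n=%d out=%s", config.n_patients, out)
    return out


def select_cohort(
    pairs: list[tuple[PlanRecord, PlanRecord]],
    covariates: list[PatientCovariates],
    registry: ModelRegistry,
    mode: str = "standard",
    clamp_negative: bool = False,
) -> list[EligibilityResult]:
    """Evaluate the registry on each plan pair and apply the MBS rules."""
    cov_by_id = {c.patient_id: c for c in covariates}
    thresholds = registry.thresholds(mode)
    weights = registry.weights()
    results = []
    for photon, proton in pairs:
        cov = cov_by_id.get(photon.patient_id)
        deltas = delta_ntcp(
            evaluate_plan(registry, photon, cov),
            evaluate_plan(registry, proton, cov),
        )
        results.append(mbs_eligibility(
            photon.patient_id, deltas, thresholds, weights,
            clamp_negative=clamp_negative,
        ))
    return results


def _paired_plans(dvh_csv, covariates_csv):
    covs, rx = read_covariates_csv(covariates_csv)
    plans = read_dvh_csv(dvh_csv, prescriptions=rx)
    by_pid: dict[str, dict[str, PlanRecord]] = {}
    for p in plans:
        by_pid.setdefault(p.patient_id, {})[p.modality] = p
    pairs = []
    for pid in sorted(by_pid):
        pair = by_pid[pid]
        if "photon" not in pair or "proton" not in pair:
            raise ValueError(f"patient {pid}: needs both a photon and a proton plan")
        pairs.append((pair["photon"], pair["proton"]))
    return covs, pairs


def run_evaluation(
    dvh_csv: str | Path,
    covariates_csv: str | Path,
    out_dir: str | Path,
    registry_path: str | Path | None = None,
) -> Path:
    """Evaluate the NTCP registry per plan; write ntcp.csv and delta.csv."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(registry_path)
    covs, pairs = _paired_plans(dvh_csv, covariates_csv)
    cov_by_id = {c.patient_id: c for c in covs}
    ntcp_rows, delta_rows = [], []
    for photon, proton in pairs:
        cov = cov_by_id.get(photon.patient_id)
        px = evaluate_plan(registry, photon, cov)
        pp = evaluate_plan(registry, proton, cov)
        for plan_ntcp in (px, pp):
            for model_id, prob in plan_ntcp.probabilities.items():
                ntcp_rows.append({
                    "patient_id": plan_ntcp.patient_id,
                    "modality": plan_ntcp.modality,
                    "model_id": model_id,
                    "ntcp": prob,
                })
        for model_id, delta in delta_ntcp(px, pp).items():
            delta_rows.append({
                "patient_id": photon.patient_id,
                "model_id": model_id,
                "delta_ntcp_pct": delta,
            })
    pd.DataFrame(ntcp_rows).to_csv(out / "ntcp.csv", index=False,
                                   float_format="%.10g")
    pd.DataFrame(delta_rows).to_csv(out / "delta.csv", index=False,
                                    float_format="%.10g")
    RunManifest(
        stage="evaluate",
        registry_hash=registry.content_hash()[:16],
        input_digests={
            "dvh_csv": _sha256_file(Path(dvh_csv)),
            "covariates_csv": _sha256_file(Path(covariates_csv)),
        },
    ).write(out)
    return out


def run_selection(
    dvh_csv: str | Path,
    covariates_csv: str | Path,
    out_dir: str | Path,
    registry_path: str | Path | None = None,
    mode: str = "standard",
    clamp_negative: bool = False,
) -> Path:
    """File-level selection run: verdict JSONs, cohort CSV, report, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(registry_path)
    covs, pairs = _paired_plans(dvh_csv, covariates_csv)
    results = select_cohort(pairs, covs, registry, mode, clamp_negative)

    manifest = RunManifest(
        stage="select",
        threshold_mode=mode,
        clamp_negative=clamp_negative,
        registry_hash=registry.content_hash()[:16],
        input_digests={
            "dvh_csv": _sha256_file(Path(dvh_csv)),
            "covariates_csv": _sha256_file(Path(covariates_csv)),
        },
    )
    verdict_dir = out / "verdicts"
    verdict_dir.mkdir(exist_ok=True)
    for r in results:
        with open(verdict_dir / f"{r.patient_id}.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(r), fh, indent=2, sort_keys=True)
            fh.write("\n")
    cohort = build_cohort_table(covs, results)
    cohort.df.to_csv(out / "cohort.csv", index=False, float_format="%.12g")
    write_report(out / "report.txt", cohort, results, registry, manifest)
    with open(out / "registry_echo.json", "w", encoding="utf-8") as fh:
        json.dump(registry.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.write(out)
    logger.info("event=selected n=%d mode=%s out=%s", len(results), mode, out)
    return out


def write_report(
    path: Path,
    cohort,
    results: list[EligibilityResult],
    registry: ModelRegistry,
    manifest: RunManifest,
) -> None:
    """Plain-text stratified report (percentages to one decimal place)."""
    counts = eligible_fraction(results)
    table = passing_rate_table(cohort)
    tests = paired_ntcp_tests(cohort)
    eligible_cts = cohort.df.loc[cohort.df["eligible"] == True, "cts"]  # noqa: E712
    non_cts = cohort.df.loc[cohort.df["eligible"] == False, "cts"]  # noqa: E712
    groups = compare_groups_cts(eligible_cts, non_cts)
    clamp = results[0].clamp_negative if results else False
    lines = [
        f"MBS selection report (manifest {manifest.hash})",
        f"threshold mode: {cohort.mode}; negative-delta handling: "
        f"{'clamped at zero' if clamp else 'sign-preserving (default)'}",
        "",
        f"cohort n = {counts.n}; eligible = {counts.union} "
        f"({round_half_up(100 * counts.fraction, 1)}%)",
        f"  single rule: {counts.single}  composite rule: {counts.composite}  "
        f"both: {counts.both}  single-only: {counts.single_only}  "
        f"composite-only: {counts.composite_only}  "
        f"not evaluable: {counts.not_evaluable}",
        "",
        "passing rates by stratum (%):",
        table.to_string(),
        "",
        "CTS by eligibility group:",
        f"  eligible     mean {groups.mean_eligible:.2f} sd {groups.sd_eligible:.2f} "
        f"(n={groups.n_eligible})",
        f"  not eligible mean {groups.mean_not_eligible:.2f} "
        f"sd {groups.sd_not_eligible:.2f} (n={groups.n_not_eligible})",
        f"  two-sided p = {groups.p_value if groups.testable else 'not testable'} "
        f"({groups.method}){'; ' + groups.note if groups.note else ''}",
        "",
        "paired delta-NTCP tests (alpha = 0.05, no multiple-testing correction):",
        tests.to_string(index=False) if not tests.empty else "  (none)",
        "",
        f"registry: {len(registry)} models, {len(registry.mbs_ids)} MBS members "
        f"(hash {manifest.registry_hash})",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
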