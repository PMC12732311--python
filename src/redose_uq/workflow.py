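"""End-to-end pipeline: register -> gate -> map dose -> uncertainty -> report.

Stage order per case:

1. one rigid pre-alignment shared by the whole ensemble;
2. the deformable registration ensemble;
3. the per-OAR mDTA plausibility gate;
4. dose mapping — fields are mapped once per registration and the per-OAR
   gate selects which mapped doses enter each organ's statistics, so dose
   is never taken from a registration deemed implausible for the organ
   being reported;
5. the three uncertainty products and cohort aggregation.

Stage failures are confined: a failing organ is recorded in the case's
failure ledger and the remaining organs still report; a failing case in a
batch is recorded and the batch completes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .dose_mapping import MappedDose, map_dose_ensemble
from .grids import CaseManifest, StructureMask, VolumeGrid
from .phantom import PhantomCase
from .plausibility import PlausibilityPolicy, PlausibilityRecord, assess_ensemble
from .registration import (
    SIX_GRID,
    SIXTEEN_GRID,
    RegistrationConfig,
    RegistrationResult,
    enumerate_ensemble,
    rigid_register,
    run_ensemble,
)
from .uncertainty import (
    DEFAULT_BIN_WIDTH_GY,
    DEFAULT_HOT_VOLUME_CC,
    CohortSummary,
    OARUncertaintyReport,
    build_report,
    summarise_cohort,
)

logger = logging.getLogger("redose_uq")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; ``grid`` is "six", "sixteen" or an explicit
    parameter mapping."""

    grid: str | dict = "six"
    threshold_cm: float = 0.3
    dvh_bin_width_gy: float = DEFAULT_BIN_WIDTH_GY
    hot_volume_cc: float = DEFAULT_HOT_VOLUME_CC
    out_dir: str | None = None
    log_level: str = "INFO"
    cache_mapped_doses: bool = True

    def __post_init__(self) -> None:
        for name in ("threshold_cm", "dvh_bin_width_gy", "hot_volume_cc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.configs():
            raise ValueError("ensemble grid resolves to no configurations")

    def configs(self) -> list[RegistrationConfig]:
        if isinstance(self.grid, dict):
            return enumerate_ensemble(self.grid)
        named = {"six": SIX_GRID, "sixteen": SIXTEEN_GRID}
        if self.grid not in named:
            raise ValueError(f"unknown grid {self.grid!r}; use 'six', 'sixteen' or a mapping")
        return enumerate_ensemble(named[self.grid])

    def digest(self) -> str:
        payload = json.dumps(
            {k: v for k, v in asdict(self).items() if k not in ("out_dir", "log_level")},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CaseInputs:
    """In-memory view of one case: the reirradiation scan is the reference
    frame, the prior scan is the moving image."""

    case_id: str
    reference: VolumeGrid
    moving: VolumeGrid
    prior_dose: VolumeGrid
    prior_masks: list[StructureMask]
    reference_masks: list[StructureMask]

    @classmethod
    def from_phantom(cls, case: PhantomCase, case_id: str | None = None) -> "CaseInputs":
        return cls(
            case_id=case_id or f"phantom_seed{case.spec.seed}_{case.spec.scenario}",
            reference=case.reirradiation_volume,
            moving=case.prior_volume,
            prior_dose=case.prior_dose,
            prior_masks=case.prior_masks,
            reference_masks=case.reirradiation_masks,
        )

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "CaseInputs":
        manifest = rio.load_manifest(manifest_path)
        pv = rio.load_volume(rio.resolve(manifest_path, manifest.prior_volume))
        pd_ = rio.load_volume(rio.resolve(manifest_path, manifest.prior_dose))
        rv = rio.load_volume(rio.resolve(manifest_path, manifest.reirradiation_volume))
        prior_masks, ref_masks = [], []
        for o in manifest.iter_oars():
            prior_masks.append(
                rio.load_mask(rio.resolve(manifest_path, o["prior_mask"]), o["name"], o["organ_class"])
            )
            ref_masks.append(
                rio.load_mask(
                    rio.resolve(manifest_path, o["reirradiation_mask"]), o["name"], o["organ_class"]
                )
            )
        return cls(manifest.case_id, rv, pv, pd_, prior_masks, ref_masks)


@dataclass
class CaseResult:
    case_id: str
    results: list[RegistrationResult]
    records: list[PlausibilityRecord]
    reports: list[OARUncertaintyReport]
    mapped_doses: dict[str, MappedDose] = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_case(inputs: CaseInputs, config: RunConfig = RunConfig()) -> CaseResult:
    """Execute the full pipeline for one case; deterministic given inputs."""
    configs = config.configs()
    policy = PlausibilityPolicy(config.threshold_cm)
    failures: list[dict] = []
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    rigid = rigid_register(inputs.reference, inputs.moving)
    timings["rigid_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results = run_ensemble(inputs.reference, inputs.moving, configs, rigid=rigid)
    timings["ensemble_s"] = time.perf_counter() - t0
    for res in results:
        if "error" in res.diagnostics:
            failures.append(
                {"stage": "registration", "config": res.config.label,
                 "error": res.diagnostics["error"]}
            )

    t0 = time.perf_counter()
    records = assess_ensemble(results, inputs.prior_masks, inputs.reference_masks, policy)
    timings["plausibility_s"] = time.perf_counter() - t0

    cache: dict[str, MappedDose] = {}
    reports: list[OARUncertaintyReport] = []
    t0 = time.perf_counter()
    for ref_mask in inputs.reference_masks:
        try:
            mapped, _ = map_dose_ensemble(
                inputs.prior_dose, results, records, ref_mask.name,
                cache=cache if config.cache_mapped_doses else None,
            )
            reports.append(
                build_report(
                    inputs.case_id, ref_mask.name, records, mapped, ref_mask,
                    config.dvh_bin_width_gy, config.hot_volume_cc,
                )
            )
        except Exception as exc:
            failures.append({"stage": "uncertainty", "oar": ref_mask.name,
                             "error": f"{type(exc).__name__}: {exc}"})
    timings["uncertainty_s"] = time.perf_counter() - t0

    result = CaseResult(inputs.case_id, results, records, reports, cache, failures, timings)
    if config.out_dir:
        write_case_result(result, config, Path(config.out_dir) / inputs.case_id)
    return result


def run_batch(
    manifests: list[CaseInputs], config: RunConfig = RunConfig()
) -> tuple[CohortSummary | None, list[CaseResult], list[dict]]:
    """Independent per-case runs plus cohort aggregation.

    Returns (summary, case results, batch-level failure ledger); a case
    failure is isolated and the batch completes.
    """
    if not manifests:
        raise ValueError("empty batch")
    case_results: list[CaseResult] = []
    batch_failures: list[dict] = []
    for item in manifests:
        try:
            inputs = item if isinstance(item, CaseInputs) else CaseInputs.from_manifest(item)
            case_results.append(run_case(inputs, config))
        except Exception as exc:
            cid = item.case_id if isinstance(item, CaseInputs) else str(item)
            batch_failures.append({"case": cid, "error": f"{type(exc).__name__}: {exc}"})
    all_reports = [r for cr in case_results for r in cr.reports]
    summary = summarise_cohort(all_reports) if all_reports else None
    return summary, case_results, batch_failures


# -- artefact writing -------------------------------------------------------


def records_frame(case_id: str, records: list[PlausibilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case": case_id,
                "config": r.config_label,
                "oar": r.oar_name,
                "mdta_cm": np.nan if r.mdta_cm is None else r.mdta_cm,
                "plausible": r.plausible,
                "reason": r.reason,
            }
            for r in records
        ]
    )


def report_to_dict(report: OARUncertaintyReport) -> dict:
    return {
        "case": report.case_id,
        "oar": report.oar_name,
        "organ_class": report.organ_class,
        "n_configs": report.n_configs,
        "n_plausible": report.n_plausible,
        "metric_kind": report.metric.metric_kind if report.metric else None,
        "metric_values_gy": report.metric.values_gy if report.metric else None,
        "metric_mean_gy": report.metric.mean_gy if report.metric else None,
        "metric_sd_gy": report.metric.sd_gy if report.metric else None,
        "invalid_voxel_fraction": report.invalid_voxel_fraction,
        "flags": report.flags,
    }


def write_case_result(result: CaseResult, config: RunConfig, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records_frame(result.case_id, result.records).to_csv(
        out_dir / "plausibility.csv", index=False, float_format="%.6f"
    )
    for res in result.results:
        rio.save_field(res.field, out_dir / f"field_{res.config.label}.nii.gz")
    for label, md in result.mapped_doses.items():
        rio.save_volume(md.dose, out_dir / f"mapped_dose_{label}.nii.gz")
    dvh_rows = []
    for rep in result.reports:
        if rep.voxel_sd is not None:
            rio.save_volume(rep.voxel_sd.sd, out_dir / f"sd_map_{rep.oar_name}.nii.gz")
        for curve in rep.dvh_ensemble:
            for edge, vol in zip(curve.bin_edges_gy, curve.rel_volume):
                dvh_rows.append(
                    {"oar": curve.oar_name, "config": curve.config_label,
                     "bin_edge_gy": float(edge), "rel_volume": float(vol)}
                )
    if dvh_rows:
        pd.DataFrame(dvh_rows).to_csv(out_dir / "dvh_ensemble.csv", index=False,
                                      float_format="%.6f")
    from . import __version__

    payload = {
        "case": result.case_id,
        "provenance": {"config_digest": config.digest(), "package_version": __version__},
        "failures": result.failures,
        "reports": [report_to_dict(r) for r in result.reports],
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_cohort_summary(summary: CohortSummary, path: str | Path) -> None:
    summary.per_case_oar.to_csv(path, index=False, float_format="%.6f")
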