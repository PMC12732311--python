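"""Uncertainty products over the plausible mapped-dose ensemble.

For each organ at risk, three products summarise how much the mapped prior
dose depends on which (plausible) registration produced it:

1. DVH-metric spread — mean and sample SD across the ensemble of D0.1cm3
   for serial organs (hot-spot surrogate) or mean dose for parallel organs;
2. the DVH curve ensemble — one cumulative dose-volume histogram per
   plausible registration;
3. a voxel-wise SD map — the per-voxel sample SD of mapped dose over the
   ensemble, inside the organ as delineated on the reirradiation scan.

Cohort-level reporting aggregates the plausibility counts and metric-SD
distributions across cases and organs.

Throughout, "SD" is the sample standard deviation (n-1 denominator), and a
single-member ensemble has its SD reported as undefined, never as 0: one
registration carries no spread information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_mapping import MappedDose
from .grids import StructureMask, VolumeGrid
from .plausibility import PlausibilityRecord

DEFAULT_BIN_WIDTH_GY = 0.1
DEFAULT_HOT_VOLUME_CC = 0.1


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the (valid) organ volume receiving at
    least each bin-edge dose."""

    oar_name: str
    config_label: str
    bin_edges_gy: np.ndarray
    rel_volume: np.ndarray

    def volume_at_dose(self, dose_gy: float) -> float:
        return float(np.interp(dose_gy, self.bin_edges_gy, self.rel_volume))


def _valid_in_mask(dose: MappedDose, mask: StructureMask) -> np.ndarray:
    sel = mask.indicator & dose.valid
    return dose.dose.values[sel]


def compute_dvh(
    dose: MappedDose, mask: StructureMask, bin_width_gy: float = DEFAULT_BIN_WIDTH_GY
) -> DVHCurve:
    """Cumulative DVH over valid in-mask voxels, volume-weighted, relative
    to the valid in-mask volume."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    vals = _valid_in_mask(dose, mask)
    if vals.size == 0:
        raise ValueError(f"no valid voxels inside mask {mask.name!r}")
    n_bins = int(np.floor(vals.max() / bin_width_gy)) + 2
    edges = np.arange(n_bins + 1) * bin_width_gy
    # uniform voxel volume on a regular grid: fractions are count ratios
    rel = np.array([np.mean(vals >= e) for e in edges])
    return DVHCurve(mask.name, dose.config_label, edges, rel)


def dose_at_volume(dose: MappedDose, mask: StructureMask, volume_cc: float) -> float:
    """Dose (Gy) to the hottest ``volume_cc`` of the organ.

    Valid in-mask voxel doses are sorted descending and voxel volumes
    accumulated; the returned dose interpolates linearly between the voxel
    doses bracketing the requested cumulative volume.
    """
    vals = _valid_in_mask(dose, mask)
    if vals.size == 0:
        raise ValueError(f"no valid voxels inside mask {mask.name!r}")
    voxel_cc = mask.grid.geometry.voxel_volume_mm3 / 1000.0
    total_cc = vals.size * voxel_cc
    if not 0 < volume_cc <= total_cc + 1e-12:
        raise ValueError(
            f"requested volume {volume_cc} cc outside (0, {total_cc:.4f}] cc of {mask.name!r}"
        )
    order = np.argsort(vals)[::-1]
    sorted_dose = vals[order]
    cum_cc = np.arange(1, vals.size + 1) * voxel_cc
    k = int(np.searchsorted(cum_cc, volume_cc, side="left"))
    if k == 0:
        return float(sorted_dose[0])
    k = min(k, vals.size - 1)
    frac = (volume_cc - cum_cc[k - 1]) / voxel_cc
    return float(sorted_dose[k - 1] + frac * (sorted_dose[k] - sorted_dose[k - 1]))


def organ_mean_dose(dose: MappedDose, mask: StructureMask) -> float:
    """Volume-weighted mean dose over valid in-mask voxels (Gy)."""
    vals = _valid_in_mask(dose, mask)
    if vals.size == 0:
        raise ValueError(f"no valid voxels inside mask {mask.name!r}")
    return float(vals.mean())


def dvh_metric(
    dose: MappedDose,
    mask: StructureMask,
    organ_class: str | None = None,
    hot_volume_cc: float = DEFAULT_HOT_VOLUME_CC,
) -> float:
    """The class-appropriate DVH metric: D<hot_volume>cm3 for serial organs,
    mean dose for parallel organs."""
    organ_class = organ_class or mask.organ_class
    if organ_class == "serial":
        return dose_at_volume(dose, mask, hot_volume_cc)
    if organ_class == "parallel":
        return organ_mean_dose(dose, mask)
    raise ValueError(f"unknown organ class {organ_class!r}")


@dataclass
class MetricStats:
    metric_kind: str  # "D0.1cm3" or "mean_dose"
    values_gy: list[float]
    mean_gy: float | None
    sd_gy: float | None  # None when n < 2 (undefined, not zero)
    n: int

    @property
    def sd_defined(self) -> bool:
        return self.sd_gy is not None


def metric_stats(
    mapped: list[MappedDose],
    mask: StructureMask,
    organ_class: str | None = None,
    hot_volume_cc: float = DEFAULT_HOT_VOLUME_CC,
) -> MetricStats:
    """Ensemble mean and sample SD of the class-appropriate DVH metric."""
    organ_class = organ_class or mask.organ_class
    kind = f"D{hot_volume_cc:g}cm3" if organ_class == "serial" else "mean_dose"
    if not mapped:
        return MetricStats(kind, [], None, None, 0)
    values = [dvh_metric(md, mask, organ_class, hot_volume_cc) for md in mapped]
    mean = float(np.mean(values))
    if len(values) < 2:
        sd = None
    elif max(values) == min(values):
        sd = 0.0  # identical members: exactly zero, not summation rounding
    else:
        sd = float(np.std(values, ddof=1))
    return MetricStats(kind, values, mean, sd, len(values))


@dataclass
class VoxelSDMap:
    sd: VolumeGrid  # Gy; 0 outside the organ and where undefined
    defined: np.ndarray  # bool: inside organ and valid in >= 2 ensemble members


def voxelwise_sd(mapped: list[MappedDose], mask: StructureMask) -> VoxelSDMap:
    """Per-voxel sample SD of mapped dose across the ensemble.

    The voxel domain is the organ as delineated on the reirradiation scan.
    Each voxel's SD uses only the registrations for which that voxel's
    mapped point was inside the prior dose grid; voxels valid in fewer than
    two members are flagged undefined.
    """
    if len(mapped) < 2:
        raise ValueError("voxel-wise SD needs at least two mapped doses")
    geom = mapped[0].dose.geometry
    inside = mask.indicator
    stack = np.stack([md.dose.values for md in mapped])
    valid = np.stack([md.valid for md in mapped])
    count = valid.sum(axis=0)
    defined = inside & (count >= 2)
    safe_count = np.maximum(count, 1)
    mean = np.where(valid, stack, 0.0).sum(axis=0) / safe_count
    sq = np.where(valid, (stack - mean) ** 2, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(sq / np.maximum(count - 1, 1))
    # identical members give exactly zero spread; the naive sum would leave
    # summation rounding at the 1e-16 level
    lo = np.where(valid, stack, np.inf).min(axis=0)
    hi = np.where(valid, stack, -np.inf).max(axis=0)
    sd = np.where(hi == lo, 0.0, sd)
    out = np.where(defined, sd, 0.0)
    return VoxelSDMap(VolumeGrid(geom, out), defined)


@dataclass
class OARUncertaintyReport:
    case_id: str
    oar_name: str
    organ_class: str
    n_configs: int
    n_plausible: int
    metric: MetricStats | None
    dvh_ensemble: list[DVHCurve] = field(default_factory=list)
    voxel_sd: VoxelSDMap | None = None
    invalid_voxel_fraction: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def mappable(self) -> bool:
        return "not_mappable" not in self.flags


def build_report(
    case_id: str,
    oar_name: str,
    records: list[PlausibilityRecord],
    mapped: list[MappedDose],
    reference_mask: StructureMask,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    hot_volume_cc: float = DEFAULT_HOT_VOLUME_CC,
) -> OARUncertaintyReport:
    """Assemble all three uncertainty products for one organ.

    ``mapped`` must already be the plausible subset for this organ (in
    ensemble order); ``records`` are this organ's records for the whole
    ensemble, used for the counts.
    """
    oar_records = [r for r in records if r.oar_name == oar_name]
    n_configs = len(oar_records)
    n_plausible = sum(r.plausible for r in oar_records)
    if len(mapped) != n_plausible:
        raise ValueError(
            f"{oar_name}: {len(mapped)} mapped doses but {n_plausible} plausible records"
        )
    flags = sorted({r.reason for r in oar_records if r.reason != "evaluated"})
    if not mapped:
        return OARUncertaintyReport(
            case_id, oar_name, reference_mask.organ_class, n_configs, n_plausible,
            None, [], None, None, flags + ["not_mappable"],
        )
    stats = metric_stats(mapped, reference_mask, hot_volume_cc=hot_volume_cc)
    if not stats.sd_defined:
        flags.append("sd_undefined_single_member")
    dvhs = [compute_dvh(md, reference_mask, bin_width_gy) for md in mapped]
    sd_map = voxelwise_sd(mapped, reference_mask) if len(mapped) >= 2 else None
    inside = reference_mask.indicator
    inv_frac = float(
        np.mean([1.0 - np.mean(md.valid[inside]) for md in mapped])
    )
    return OARUncertaintyReport(
        case_id, oar_name, reference_mask.organ_class, n_configs, n_plausible,
        stats, dvhs, sd_map, inv_frac, flags,
    )


@dataclass
class CohortSummary:
    """Plausibility counts and metric-SD spread, discriminated by case and OAR."""

    per_case_oar: pd.DataFrame  # case, oar, organ_class, n_plausible, n_configs, metric_sd
    percent_plausible_overall: float
    percent_plausible_per_case: pd.Series
    percent_plausible_per_oar: pd.Series
    sd_distribution_per_oar: pd.DataFrame  # min, q1, median, q3, max, outliers


def summarise_cohort(reports: list[OARUncertaintyReport]) -> CohortSummary:
    if not reports:
        raise ValueError("no reports to summarise")
    rows = [
        {
            "case": r.case_id,
            "oar": r.oar_name,
            "organ_class": r.organ_class,
            "n_plausible": r.n_plausible,
            "n_configs": r.n_configs,
            "metric_sd_gy": r.metric.sd_gy if r.metric is not None else np.nan,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    overall = 100.0 * df["n_plausible"].sum() / df["n_configs"].sum()
    per_case = 100.0 * df.groupby("case")["n_plausible"].sum() / df.groupby("case")[
        "n_configs"
    ].sum()
    per_oar = 100.0 * df.groupby("oar")["n_plausible"].sum() / df.groupby("oar")[
        "n_configs"
    ].sum()
    dist_rows = []
    for oar, grp in df.groupby("oar"):
        sds = grp["metric_sd_gy"].dropna().to_numpy()
        if sds.size == 0:
            dist_rows.append({"oar": oar, "n": 0})
            continue
        q1, med, q3 = np.percentile(sds, [25, 50, 75])
        iqr = q3 - q1
        outliers = sds[(sds < q1 - 1.5 * iqr) | (sds > q3 + 1.5 * iqr)]
        dist_rows.append(
            {
                "oar": oar,
                "n": int(sds.size),
                "min": float(sds.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(sds.max()),
                "outliers": list(map(float, outliers)),
            }
        )
    dist = pd.DataFrame(dist_rows).set_index("oar")
    return CohortSummary(df, float(overall), per_case, per_oar, dist)
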