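"""Structure mapping, mean distance to agreement, and the local
plausibility gate.

A registration is judged *locally*: the prior-course delineation of each
organ at risk is warped onto the reirradiation frame through the
registration's field and compared with the delineation on the
reirradiation scan using the mean distance to agreement (mDTA).  A
registration passes for an OAR when mDTA <= 0.3 cm (inclusive), the
TG-132 tolerance; the same registration can pass for one organ and fail
for its neighbour — that locality is the point of the gate.

mDTA here is the symmetric mean surface distance: the mean, over the union
of both voxelised surfaces' points, of the Euclidean distance to the other
surface.  Surfaces are face-connected (6-neighbourhood) boundary voxels;
distances come from a Euclidean distance transform with physical spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import DeformationField, StructureMask, VolumeGrid, sample_volume
from .registration import RegistrationResult


@dataclass(frozen=True)
class PlausibilityPolicy:
    """The inclusive mDTA gate; 0.3 cm per TG-132."""

    threshold_cm: float = 0.3

    def __post_init__(self) -> None:
        if self.threshold_cm <= 0:
            raise ValueError("threshold must be positive")

    def passes(self, mdta_cm: float) -> bool:
        return mdta_cm <= self.threshold_cm


@dataclass
class PlausibilityRecord:
    config_label: str
    oar_name: str
    mdta_cm: float | None
    plausible: bool
    mapped_mask_empty: bool = False
    reason: str = "evaluated"


def warp_mask(prior_mask: StructureMask, field: DeformationField) -> StructureMask:
    """Pull the prior-scan mask onto the reference frame through ``field``.

    Each reference voxel samples the prior mask at its mapped point with
    linear interpolation; occupancy is thresholded at 0.5.  Points mapping
    outside the prior extent contribute 0.
    """
    vals, _ = sample_volume(prior_mask.grid, field.mapped_points(), "linear", 0.0)
    warped = (vals >= 0.5).astype(float)
    return StructureMask(
        prior_mask.name,
        prior_mask.organ_class,
        VolumeGrid(field.geometry, warped),
        allow_empty=True,
    )


def extract_surface(mask: StructureMask) -> np.ndarray:
    """Physical centers (mm) of surface voxels: foreground voxels with a
    face-adjacent background or out-of-grid neighbour.  Shape (n, 3)."""
    if mask.is_empty:
        raise ValueError(f"mask {mask.name!r} is empty; no surface")
    surf = _surface_voxels(mask.indicator)
    idx = np.argwhere(surf)
    return mask.grid.geometry.to_physical(idx)


def _surface_voxels(fg: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    # border_value=0: outside the grid counts as background
    interior = ndimage.binary_erosion(fg, structure=structure, border_value=0)
    return fg & ~interior


def mdta(mask_a: StructureMask, mask_b: StructureMask) -> float:
    """Symmetric mean surface distance between two masks, in cm.

    Mean over the union of both directed surface point sets (so each
    direction is weighted by its surface-point count) of the distance to
    the other surface, computed by Euclidean distance transform on the
    common grid.  Zero iff the voxelised surfaces coincide.
    """
    ga, gb = mask_a.grid.geometry, mask_b.grid.geometry
    if ga != gb:
        raise ValueError("mDTA requires masks on the same grid")
    if mask_a.is_empty or mask_b.is_empty:
        raise ValueError("mDTA undefined for empty masks")
    surf_a = _surface_voxels(mask_a.indicator)
    surf_b = _surface_voxels(mask_b.indicator)
    spacing = ga.spacing
    dist_to_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~surf_a, sampling=spacing)
    d_ab = dist_to_b[surf_a]
    d_ba = dist_to_a[surf_b]
    mean_mm = float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))
    return mean_mm / 10.0


def assess_ensemble(
    results: list[RegistrationResult],
    prior_masks: list[StructureMask],
    reference_masks: list[StructureMask],
    policy: PlausibilityPolicy = PlausibilityPolicy(),
) -> list[PlausibilityRecord]:
    """One plausibility record per (registration, OAR).

    An absent or empty reirradiation mask, or a warped mask that vanishes,
    yields plausible=False with a distinct reason code rather than a large
    distance — anatomical absence is not the same failure as misalignment.
    """
    ref_by_name = {m.name: m for m in reference_masks}
    records: list[PlausibilityRecord] = []
    for result in results:
        for pm in prior_masks:
            label = result.config.label
            ref = ref_by_name.get(pm.name)
            if ref is None or ref.is_empty:
                records.append(
                    PlausibilityRecord(label, pm.name, None, False, False, "reference_mask_empty")
                )
                continue
            warped = warp_mask(pm, result.field)
            if warped.is_empty:
                records.append(
                    PlausibilityRecord(label, pm.name, None, False, True, "mapped_mask_empty")
                )
                continue
            value = mdta(warped, ref)
            records.append(
                PlausibilityRecord(label, pm.name, value, policy.passes(value), False)
            )
    return records
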