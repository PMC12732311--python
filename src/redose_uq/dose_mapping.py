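"""Mapping the prior-course dose onto the reirradiation frame.

Dose mapping is a pull-back: the mapped dose at a reirradiation voxel is
the prior dose grid sampled, with trilinear interpolation, at that voxel's
mapped point.  This is interpolation, not energy transport — integral dose
is *not* conserved under a non-rigid field, and nothing downstream assumes
it is.  Only physical dose is handled; no fractionation or EQD2
conversion is applied.

Reference voxels whose mapped point falls outside the prior dose extent
are marked invalid (stored as 0 Gy) and are excluded from every DVH,
metric and SD computation downstream; silently treating them as 0 Gy
would bias mean doses low when the prior scan does not cover the full
reirradiation field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DeformationField, VolumeGrid, sample_volume
from .plausibility import PlausibilityRecord
from .registration import RegistrationResult


@dataclass
class MappedDose:
    config_label: str
    dose: VolumeGrid  # Gy, on the reference geometry
    valid: np.ndarray  # bool per voxel: mapped point inside the prior dose extent

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - np.mean(self.valid))


def map_dose(
    prior_dose: VolumeGrid, field: DeformationField, config_label: str = ""
) -> MappedDose:
    """Pull the prior dose through a deformation field.

    The prior dose is sampled in its native geometry at the field's mapped
    points (the rigid part is already composed into the field), avoiding a
    double interpolation through the prior CT grid.
    """
    vals, valid = sample_volume(prior_dose, field.mapped_points(), "linear", 0.0)
    vals = np.where(valid, vals, 0.0)
    return MappedDose(config_label, VolumeGrid(field.geometry, vals), valid)


def map_dose_ensemble(
    prior_dose: VolumeGrid,
    results: list[RegistrationResult],
    records: list[PlausibilityRecord],
    oar: str,
    cache: dict[str, MappedDose] | None = None,
) -> tuple[list[MappedDose], bool]:
    """Mapped doses for exactly the registrations plausible for ``oar``.

    Returns ``(mapped_doses, mappable)``; an OAR with zero plausible
    registrations gets an empty list and ``mappable=False``.  Dose mapping
    is computed once per registration and shared across OARs via ``cache``
    (keyed by config label) — the per-OAR gate only selects which mapped
    doses enter the statistics.
    """
    plausible = {
        r.config_label for r in records if r.oar_name == oar and r.plausible
    }
    seen = {r.config_label for r in records if r.oar_name == oar}
    missing = {res.config.label for res in results} - seen
    if missing:
        raise ValueError(f"plausibility records missing for configs {sorted(missing)}")
    mapped: list[MappedDose] = []
    for res in results:
        label = res.config.label
        if label not in plausible:
            continue
        if cache is not None and label in cache:
            mapped.append(cache[label])
            continue
        md = map_dose(prior_dose, res.field, label)
        if cache is not None:
            cache[label] = md
        mapped.append(md)
    return mapped, bool(mapped)
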