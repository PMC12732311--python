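"""NIfTI and JSON manifest I/O.

Volumes, doses, masks and displacement fields all travel as NIfTI
(.nii/.nii.gz) with a diagonal affine: ``affine = diag(spacing) @ [origin]``.
Displacement fields are stored as 4-D volumes with the three displacement
components (mm, in grid-axis order) along the last dimension; the header
description records this layout.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import (
    CaseManifest,
    DeformationField,
    GridGeometry,
    StructureMask,
    VolumeGrid,
)

FIELD_LAYOUT_NOTE = b"displacement mm, components along dim 4 in axis order"


def _affine(geometry: GridGeometry) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(geometry.spacing)
    aff[:3, 3] = geometry.origin
    return aff


def _geometry_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> GridGeometry:
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("oblique NIfTI affines are not supported (axis-aligned grids only)")
    spacing = tuple(float(v) for v in np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise ValueError("negative or zero spacing in NIfTI affine")
    origin = tuple(float(v) for v in affine[:3, 3])
    return GridGeometry(origin, spacing, tuple(int(v) for v in shape[:3]))


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.geometry))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VolumeGrid(_geometry_from_affine(img.affine, data.shape), data)


def save_mask(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.grid.values.astype(np.uint8), _affine(mask.grid.geometry)
    )
    nib.save(img, str(path))


def load_mask(
    path: str | Path, name: str, organ_class: str, allow_empty: bool = True
) -> StructureMask:
    vol = load_volume(path)
    vol.values = (vol.values > 0.5).astype(float)
    return StructureMask(name, organ_class, vol, allow_empty=allow_empty)


def save_field(field: DeformationField, path: str | Path) -> None:
    img = nib.Nifti1Image(field.displacement.astype(np.float32), _affine(field.geometry))
    img.header["descrip"] = FIELD_LAYOUT_NOTE
    img.header.set_intent("vector")
    nib.save(img, str(path))


def load_field(path: str | Path) -> DeformationField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention pads dim 4
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 3-component displacement field")
    return DeformationField(_geometry_from_affine(img.affine, data.shape), data)


def save_manifest(manifest: CaseManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_manifest(path: str | Path) -> CaseManifest:
    with open(path) as fh:
        data = json.load(fh)
    data.pop("schema_version", None)
    manifest = CaseManifest(schema_version=1, **data)
    base = Path(path).parent
    for rel in [manifest.prior_volume, manifest.prior_dose, manifest.reirradiation_volume] + [
        p for o in manifest.oars for p in (o["prior_mask"], o["reirradiation_mask"])
    ]:
        if not (base / rel).exists() and not Path(rel).exists():
            raise FileNotFoundError(f"manifest {manifest.case_id}: missing file {rel}")
    return manifest


def resolve(manifest_path: str | Path, rel: str) -> Path:
    """Resolve a manifest-relative path."""
    cand = Path(manifest_path).parent / rel
    return cand if cand.exists() else Path(rel)
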