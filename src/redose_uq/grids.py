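"""Physically located 3-D grids, masks, and rigid transforms.

All geometry is axis-aligned: a voxel index ``(i, j, k)`` has its center at
``origin + (i, j, k) * spacing`` in millimetres.  There are no oblique
direction matrices; planning CTs and the synthetic phantoms used here are
axial by construction.  Internal units are mm (and Gy for dose values);
surface-distance results are converted to cm only at the reporting surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised for degenerate or mismatched grid geometry."""


@dataclass(frozen=True)
class GridGeometry:
    """Origin (mm), per-axis spacing (mm) and voxel counts of a 3-D grid."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.size) != 3:
            raise GeometryError("geometry must be three-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise GeometryError(f"size must be >= 1 per axis, got {self.size}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "size", tuple(int(v) for v in self.size))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of all voxels, shape ``size + (3,)``, mm."""
        axes = [
            self.origin[a] + np.arange(self.size[a]) * self.spacing[a]
            for a in range(3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)

    def to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel index of physical points (mm), same leading shape."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def to_physical(self, index: np.ndarray) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounds spanned by voxel centers: (low, high), mm."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.size) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class VolumeGrid:
    """Axis-aligned scalar field: image intensity, dose (Gy), or distance."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.size:
            raise GeometryError(
                f"values shape {self.values.shape} != geometry size {self.geometry.size}"
            )

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VolumeGrid":
        values = np.asarray(values, dtype=float)
        return cls(GridGeometry(origin, spacing, values.shape), values)

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.geometry, self.values.copy())


OrganClass = Literal["serial", "parallel"]


@dataclass
class StructureMask:
    """Named binary organ-at-risk mask tagged serial or parallel.

    Serial organs are summarised by D0.1cm3 (hot-spot dose), parallel organs
    by the mean dose.
    """

    name: str
    organ_class: OrganClass
    grid: VolumeGrid
    allow_empty: bool = False

    def __post_init__(self) -> None:
        vals = np.unique(self.grid.values)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError(f"mask {self.name!r} has non-binary values")
        if self.organ_class not in ("serial", "parallel"):
            raise ValueError(f"unknown organ class {self.organ_class!r}")
        if self.is_empty and not self.allow_empty:
            raise ValueError(f"mask {self.name!r} is empty and not flagged as such")

    @property
    def is_empty(self) -> bool:
        return not bool(np.any(self.grid.values))

    @property
    def indicator(self) -> np.ndarray:
        return self.grid.values > 0.5


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF transform: rotate (intrinsic z-y-x Euler, radians) about
    ``center`` then translate.  ``apply`` maps reference-frame points into
    the moving frame."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (pts - c) @ self.matrix().T + c + t

    def inverse(self) -> "RigidTransform":
        # Same center; invert rotation and solve for the translation that
        # undoes apply().  R^-1 has no clean Euler split here, so represent
        # the inverse via a matrix-backed transform.
        return _MatrixRigid(self.matrix().T, self._inverse_translation(), self.center)

    def _inverse_translation(self) -> tuple[float, float, float]:
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        # apply(x) = R(x-c)+c+t ; inverse: R^T(y - c - t) + c
        # expressed as R^T(y-c)+c+t' with t' = R^T(-t) ... direct algebra:
        tinv = -self.matrix().T @ t
        return tuple(float(v) for v in tinv)

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.rotation, 0.0, atol=1e-15)
            and np.allclose(self.translation, 0.0, atol=1e-15)
        )


class _MatrixRigid(RigidTransform):
    """Rigid transform backed by an explicit rotation matrix (for inverses)."""

    def __init__(self, matrix: np.ndarray, translation, center) -> None:
        object.__setattr__(self, "rotation", (0.0, 0.0, 0.0))
        object.__setattr__(self, "translation", tuple(float(v) for v in translation))
        object.__setattr__(self, "center", tuple(float(v) for v in center))
        object.__setattr__(self, "_matrix", np.asarray(matrix, dtype=float))

    def matrix(self) -> np.ndarray:  # noqa: D102
        return self._matrix


def apply_rigid(point_mm: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Rotate-then-translate physical points (mm) about the transform center."""
    return transform.apply(point_mm)


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) on the reference (reirradiation) grid.

    Convention: mapped point = reference voxel center + displacement, with
    the displacement expressed in the prior scan's (rigidly pre-aligned)
    frame.  ``displacement`` has shape ``size + (3,)``.
    """

    geometry: GridGeometry
    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.shape != self.geometry.size + (3,):
            raise GeometryError(
                f"displacement shape {self.displacement.shape} incompatible with "
                f"geometry size {self.geometry.size}"
            )

    @classmethod
    def zero(cls, geometry: GridGeometry) -> "DeformationField":
        return cls(geometry, np.zeros(geometry.size + (3,)))

    def mapped_points(self) -> np.ndarray:
        """Physical target point for every reference voxel, mm."""
        return self.geometry.voxel_centers() + self.displacement

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacement, axis=-1)

    def compose_rigid(self, rigid: RigidTransform) -> "DeformationField":
        """Return the field whose mapping is ``rigid(x + displacement(x))``.

        Composing a zero field with a rigid pre-alignment reproduces the
        rigid mapping exactly.
        """
        centers = self.geometry.voxel_centers()
        mapped = rigid.apply((centers + self.displacement).reshape(-1, 3))
        disp = mapped.reshape(self.displacement.shape) - centers
        return DeformationField(self.geometry, disp)

    def jacobian_determinant(self) -> np.ndarray:
        """Determinant of d(mapped point)/dx on the grid (central differences)."""
        sp = self.geometry.spacing
        jac = np.empty(self.geometry.size + (3, 3))
        for comp in range(3):
            for axis in range(3):
                jac[..., comp, axis] = np.gradient(
                    self.displacement[..., comp], sp[axis], axis=axis
                )
            jac[..., comp, comp] += 1.0
        return np.linalg.det(jac)


def sample_volume(
    source: VolumeGrid,
    points_mm: np.ndarray,
    interpolation: Literal["linear", "nearest"] = "linear",
    outside_value: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a volume at arbitrary physical points.

    Returns ``(values, valid)`` where ``valid`` marks points inside the
    source's physical extent (the box spanned by voxel centers).  Outside
    points take ``outside_value``.
    """
    pts = np.asarray(points_mm, dtype=float)
    lead_shape = pts.shape[:-1]
    idx = source.geometry.to_index(pts.reshape(-1, 3))
    n = np.asarray(source.geometry.size)
    eps = 1e-9
    valid = np.all((idx >= -eps) & (idx <= n - 1 + eps), axis=1)
    order = 1 if interpolation == "linear" else 0
    vals = ndimage.map_coordinates(
        source.values, idx.T, order=order, mode="nearest", prefilter=False
    )
    vals = np.where(valid, vals, outside_value)
    return vals.reshape(lead_shape), valid.reshape(lead_shape)


def resample(
    source: VolumeGrid,
    target_geometry: GridGeometry,
    interpolation: Literal["linear", "nearest"] = "linear",
    outside_value: float = 0.0,
) -> tuple[VolumeGrid, np.ndarray]:
    """Resample ``source`` onto ``target_geometry`` by sampling at each target
    voxel center.  Returns the resampled grid and a validity mask marking
    target voxels whose center lies inside the source extent."""
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    centers = target_geometry.voxel_centers()
    vals, valid = sample_volume(source, centers, interpolation, outside_value)
    return VolumeGrid(target_geometry, vals), valid


def mask_volume_cc(mask: StructureMask) -> tuple[float, bool]:
    """Mask volume in cm3 (voxel count x voxel volume); flags empty masks.

    Returns ``(volume_cc, is_empty)``.
    """
    n = int(np.count_nonzero(mask.grid.values))
    vol_cc = n * mask.grid.geometry.voxel_volume_mm3 / 1000.0
    return vol_cc, n == 0


@dataclass
class CaseManifest:
    """File-level description of one case: volumes, dose and paired masks."""

    case_id: str
    prior_volume: str
    prior_dose: str
    reirradiation_volume: str
    oars: list[dict] = field(default_factory=list)
    schema_version: int = 1

    def __post_init__(self) -> None:
        names = [o["name"] for o in self.oars]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate OAR names in case {self.case_id!r}")
        for o in self.oars:
            if o["organ_class"] not in ("serial", "parallel"):
                raise ValueError(f"unknown organ class for OAR {o['name']!r}")

    def iter_oars(self) -> Iterator[dict]:
        return iter(self.oars)
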