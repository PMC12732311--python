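"""Synthetic paired-scan phantoms with analytic ground truth.

Each case provides a "prior" scan, a "reirradiation" scan related to it by a
known deformation, an analytic prior dose, and organ masks on both scans —
the inputs a reirradiation dose-accumulation workflow sees clinically, but
with exact oracles for every downstream stage.

Everything is defined analytically (sums of low-frequency cosines, smooth
compact blobs, anisotropic Gaussian dose kernels, compact-support C2
displacement bumps), so the reirradiation scan is the prior intensity
function evaluated exactly at deformed points: no interpolation error
enters the ground truth.

Scenarios
---------
identity
    Zero deformation; both scans identical.
rigid_offset
    The two scans differ by a known rigid transform only.
smooth_deformation
    A diffeomorphic sum of displacement bumps with a chosen peak amplitude.
tissue_disappearance
    As smooth_deformation, but one designated organ is ablated on the
    reirradiation scan: its image region reverts to background intensity
    and its mask shrinks to a small remnant.  This emulates response /
    resection between courses, the failure mode local plausibility
    filtering exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Literal

import numpy as np

from .grids import (
    CaseManifest,
    DeformationField,
    GridGeometry,
    RigidTransform,
    StructureMask,
    VolumeGrid,
)
from . import io as rio

Scenario = Literal["identity", "rigid_offset", "smooth_deformation", "tissue_disappearance"]

# Fixed intensity model (arbitrary HU-like units): contrast for CC and MI,
# absolute calibration irrelevant.
BACKGROUND_RANGE = (-50.0, 50.0)
SOFT_RANGE = (20.0, 120.0)
BONE_RANGE = (700.0, 1200.0)

#: in-plane / slice spacing matching a clinical head-and-neck planning CT
CLINICAL_ASPECT_SPACING = (0.8, 0.8, 2.5)


@dataclass(frozen=True)
class OrganSpec:
    """One organ: analytic shape in the prior frame plus its DVH class."""

    name: str
    shape: Literal["sphere", "ellipsoid", "tube"]
    center: tuple[float, float, float]  # mm
    radii: tuple[float, float, float]  # mm; sphere uses radii[0], tube (r, r, half-length)
    organ_class: Literal["serial", "parallel"]


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    size: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    scenario: Scenario = "smooth_deformation"
    amplitude_mm: float = 6.0
    organs: tuple[OrganSpec, ...] | None = None  # None -> default layout
    ablated_organ: str | None = None  # default: first organ

    def geometry(self) -> GridGeometry:
        return GridGeometry((0.0, 0.0, 0.0), self.spacing, self.size)


def default_organ_layout(geometry: GridGeometry) -> tuple[OrganSpec, ...]:
    """Three organs placed at fixed fractions of the volume extent.

    ``oar_focal`` sits inside the deformation/ablation region; ``oar_distant``
    is well separated from it (the pair demonstrates locality of the
    plausibility gate); ``oar_cord`` is a serial tube along z.
    """
    lo, hi = geometry.extent_mm()
    ext = hi - lo
    m = float(np.min(ext))

    def at(fx, fy, fz):
        return tuple(float(v) for v in lo + np.array([fx, fy, fz]) * ext)

    return (
        OrganSpec("oar_focal", "sphere", at(0.40, 0.40, 0.46), (0.11 * m,) * 3, "parallel"),
        OrganSpec("oar_distant", "sphere", at(0.72, 0.68, 0.62), (0.085 * m,) * 3, "parallel"),
        OrganSpec("oar_cord", "tube", at(0.26, 0.64, 0.50), (0.045 * m, 0.045 * m, 0.24 * m), "serial"),
    )


# ---------------------------------------------------------------------------
# analytic building blocks


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _organ_level(organ: OrganSpec, pts: np.ndarray) -> np.ndarray:
    """Normalised level-set coordinate: <1 inside, 1 on the surface."""
    d = pts - np.asarray(organ.center)
    if organ.shape == "sphere":
        return np.linalg.norm(d, axis=-1) / organ.radii[0]
    if organ.shape == "ellipsoid":
        return np.sqrt(np.sum((d / np.asarray(organ.radii)) ** 2, axis=-1))
    if organ.shape == "tube":
        radial = np.linalg.norm(d[..., :2], axis=-1) / organ.radii[0]
        axial = np.abs(d[..., 2]) / organ.radii[2]
        return np.maximum(radial, axial)
    raise ValueError(f"unknown shape {organ.shape!r}")


def organ_indicator(organ: OrganSpec, pts: np.ndarray) -> np.ndarray:
    return (_organ_level(organ, pts) <= 1.0).astype(float)


def _soft_profile(level: np.ndarray, edge: float = 0.15) -> np.ndarray:
    """1 inside, C1 taper to 0 across the surface; keeps image gradients finite."""
    return _smoothstep((1.0 + edge - level) / (2.0 * edge))


#: fraction of the bump radius occupied by the C2 taper band
BUMP_TAPER = 0.45


def _smootherstep(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: C2, 0 at t<=0, 1 at t>=1, max slope 1.875."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


@dataclass(frozen=True)
class _Bump:
    """C2 compact-support displacement bump with a flat core.

    u(x) = A * p(|x-c|/R) * dir with p = 1 on the core (s <= 1 - taper),
    a quintic C2 taper to exactly 0 at s = 1, and 0 outside.  The peak
    displacement over the support is exactly A; max |grad u| is
    1.875 * A / (taper * R), so R >= 2.1 * A / taper keeps the map
    diffeomorphic.
    """

    center: np.ndarray
    radius: float
    amplitude: float
    direction: np.ndarray

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        s = np.sqrt(np.sum(((pts - self.center) / self.radius) ** 2, axis=-1))
        prof = _smootherstep((1.0 - s) / BUMP_TAPER)
        return (self.amplitude * prof)[..., None] * self.direction


@dataclass(frozen=True)
class _GaussianDose:
    peak_gy: float
    center: np.ndarray
    sigmas: np.ndarray

    def dose(self, pts: np.ndarray) -> np.ndarray:
        z = (pts - self.center) / self.sigmas
        return self.peak_gy * np.exp(-0.5 * np.sum(z * z, axis=-1))


# ---------------------------------------------------------------------------
# the phantom case


@dataclass
class PhantomCase:
    """Generated phantom with both rasterised grids and the analytic oracles."""

    spec: PhantomSpec
    geometry: GridGeometry
    prior_volume: VolumeGrid
    reirradiation_volume: VolumeGrid
    prior_dose: VolumeGrid
    true_field: DeformationField  # rasterised total displacement (reference -> prior)
    true_rigid: RigidTransform
    prior_masks: list[StructureMask]
    reirradiation_masks: list[StructureMask]
    change_log: list[str]
    bumps: list = dc_field(default_factory=list)  # (center, radius, peak_mm, direction)
    # analytic callables retained for oracle use
    intensity_at: Callable[[np.ndarray], np.ndarray] = dc_field(repr=False, default=None)
    dose_at: Callable[[np.ndarray], np.ndarray] = dc_field(repr=False, default=None)
    displacement_at: Callable[[np.ndarray], np.ndarray] = dc_field(repr=False, default=None)

    def mask(self, name: str, prior: bool = False) -> StructureMask:
        pool = self.prior_masks if prior else self.reirradiation_masks
        for m in pool:
            if m.name == name:
                return m
        raise KeyError(name)


def evaluate_true_field(case: PhantomCase, point_mm: np.ndarray) -> np.ndarray:
    """Analytic ground-truth displacement at physical points (mm).

    This is the closed form, not an interpolation of the stored grid, so it
    serves as the registration-error oracle at arbitrary points.
    """
    pts = np.asarray(point_mm, dtype=float)
    lo, hi = case.geometry.extent_mm()
    flat = pts.reshape(-1, 3)
    if np.any(flat < lo - 1e-9) or np.any(flat > hi + 1e-9):
        raise ValueError("point outside the phantom extent")
    return case.displacement_at(pts)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build a phantom case; bit-identical for identical specs.

    RNG draw order (one seeded generator per case; order is frozen so that
    later additions do not shift existing fixtures): background cosine
    coefficients, bone landmark intensities, organ intensities, dose-blob
    parameters, bump directions.
    """
    geometry = spec.geometry()
    lo, hi = geometry.extent_mm()
    ext = hi - lo
    organs = tuple(spec.organs) if spec.organs is not None else default_organ_layout(geometry)
    if len({o.name for o in organs}) != len(organs):
        raise ValueError("organ names must be unique")
    for o in organs:
        c = np.asarray(o.center)
        r = np.asarray(o.radii)
        if np.any(c - r < lo - 1e-9) or np.any(c + r > hi + 1e-9):
            raise ValueError(f"organ {o.name!r} extends outside the volume extent")
    if spec.amplitude_mm < 0:
        raise ValueError("deformation amplitude must be >= 0")

    rng = np.random.default_rng(spec.seed)
    change_log: list[str] = [f"scenario={spec.scenario}"]

    # -- background: seeded sum of low-frequency cosines, analytic everywhere
    n_waves = 6
    amps = rng.uniform(-1.0, 1.0, size=n_waves)
    freqs = rng.uniform(0.5, 2.0, size=(n_waves, 3))  # cycles across the extent
    phases = rng.uniform(0.0, 2 * np.pi, size=n_waves)
    bg_scale = BACKGROUND_RANGE[1] / max(np.sum(np.abs(amps)), 1e-12)

    def background(pts: np.ndarray) -> np.ndarray:
        u = (pts - lo) / ext  # unitless [0,1] inside the volume
        out = np.zeros(pts.shape[:-1])
        for w in range(n_waves):
            out += amps[w] * np.cos(2 * np.pi * np.sum(freqs[w] * u, axis=-1) + phases[w])
        return bg_scale * out

    # -- bone landmarks: three non-collinear high-intensity spheres for the
    #    rigid stage to lock onto
    bone_frac = np.array([[0.20, 0.20, 0.25], [0.78, 0.26, 0.32], [0.26, 0.76, 0.70]])
    bone_centers = lo + bone_frac * ext
    bone_radius = 0.055 * float(np.min(ext))
    bone_intens = rng.uniform(*BONE_RANGE, size=len(bone_centers))
    organ_intens = rng.uniform(*SOFT_RANGE, size=len(organs))

    # -- analytic dose: anisotropic Gaussian blobs around the focal organ
    n_blobs = 2
    blob_peaks = rng.uniform(30.0, 60.0, size=n_blobs)
    blob_off = rng.uniform(-0.06, 0.06, size=(n_blobs, 3)) * ext
    blob_sigmas = rng.uniform(0.10, 0.22, size=(n_blobs, 3)) * ext
    dose_anchor = np.asarray(organs[0].center)
    dose_blobs = [
        _GaussianDose(blob_peaks[b], dose_anchor + blob_off[b], blob_sigmas[b])
        for b in range(n_blobs)
    ]

    def dose_at(pts: np.ndarray) -> np.ndarray:
        return sum(b.dose(np.asarray(pts, dtype=float)) for b in dose_blobs)

    # -- true deformation: compact C2 bumps (disjoint supports; peak of the
    #    primary bump equals the spec amplitude)
    bumps: list[_Bump] = []
    bump_dirs = rng.normal(size=(2, 3))
    bump_dirs /= np.linalg.norm(bump_dirs, axis=1, keepdims=True)
    if spec.scenario in ("smooth_deformation", "tissue_disappearance") and spec.amplitude_mm > 0:
        a = spec.amplitude_mm
        # flat-core bump: diffeomorphic for R >= 2.1 A / taper (~4.7 A)
        r1 = max(4.7 * a, 0.55 * float(np.min(ext)))
        c1 = (lo + hi) / 2.0 + np.array([0.04, -0.03, 0.02]) * ext
        bumps.append(_Bump(c1, r1, a, bump_dirs[0]))
        change_log.append(f"bumps={len(bumps)} amplitude={a} mm support={r1:.1f} mm")

    rigid = RigidTransform()
    if spec.scenario == "rigid_offset":
        rigid = RigidTransform(
            rotation=(0.0, 0.0, np.deg2rad(3.0)),
            translation=(5.0, -3.0, 2.0),
            center=tuple((lo + hi) / 2.0),
        )
        change_log.append("rigid offset: 3 deg about z, (5,-3,2) mm translation")

    # bone is rigid anatomy: the deformable component is damped to zero in
    # a C2 shell around each bone landmark, so only the rigid part moves
    # the skeleton (and the rigid pre-alignment stays well posed)
    damp_inner = bone_radius + 2.0
    damp_outer = damp_inner + 20.0

    def rigidity(pts: np.ndarray) -> np.ndarray:
        d = np.ones(pts.shape[:-1])
        for c in bone_centers:
            r = np.linalg.norm(pts - c, axis=-1)
            d = d * _smootherstep((r - damp_inner) / (damp_outer - damp_inner))
        return d

    def mapping(pts: np.ndarray) -> np.ndarray:
        """Total reference -> prior mapping: rigid plus bone-damped bumps."""
        pts = np.asarray(pts, dtype=float)
        out = rigid.apply(pts.reshape(-1, 3)).reshape(pts.shape)
        if bumps:
            damp = rigidity(pts)[..., None]
            for b in bumps:
                out = out + b.displacement(pts) * damp
        return out

    def displacement_at(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return mapping(pts) - pts

    # -- intensity functions (prior frame); ablation swaps one organ's blob
    ablated = None
    remnant: OrganSpec | None = None
    if spec.scenario == "tissue_disappearance":
        name = spec.ablated_organ or organs[0].name
        ablated = next(o for o in organs if o.name == name)
        r = ablated.radii[0]
        remnant = OrganSpec(
            ablated.name,
            "sphere",
            tuple(np.asarray(ablated.center) + np.array([0.0, 0.0, 0.5 * r])),
            (0.35 * r,) * 3,
            ablated.organ_class,
        )
        change_log.append(
            f"ablated organ {name!r}: image region reverts to background, "
            f"mask shrunk to remnant radius {remnant.radii[0]:.1f} mm"
        )

    def intensity(pts: np.ndarray, organ_set) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = background(pts)
        for o, v in zip(organ_set, organ_intens):
            out = out + v * _soft_profile(_organ_level(o, pts))
        for c, v in zip(bone_centers, bone_intens):
            lev = np.linalg.norm(pts - c, axis=-1) / bone_radius
            out = out + v * _soft_profile(lev)
        return out

    prior_intensity = lambda pts: intensity(pts, organs)  # noqa: E731
    if remnant is not None:
        reirr_organs = tuple(remnant if o.name == ablated.name else o for o in organs)
    else:
        reirr_organs = organs
    reirr_intensity = lambda pts: intensity(mapping(pts), reirr_organs)  # noqa: E731

    centers = geometry.voxel_centers()
    prior_volume = VolumeGrid(geometry, prior_intensity(centers))
    reirr_volume = VolumeGrid(geometry, reirr_intensity(centers))
    prior_dose = VolumeGrid(geometry, dose_at(centers))

    disp = displacement_at(centers)
    true_field = DeformationField(geometry, disp)
    jac = true_field.jacobian_determinant()
    if np.any(jac <= 0):
        raise ValueError(
            f"deformation folds: min Jacobian determinant {jac.min():.3f} <= 0 "
            f"(amplitude {spec.amplitude_mm} mm too large for the bump support)"
        )

    prior_masks = [
        StructureMask(o.name, o.organ_class, VolumeGrid(geometry, organ_indicator(o, centers)))
        for o in organs
    ]
    mapped_centers = mapping(centers)
    reirr_masks = [
        StructureMask(
            o.name,
            o.organ_class,
            VolumeGrid(geometry, organ_indicator(o, mapped_centers)),
            allow_empty=True,
        )
        for o in reirr_organs
    ]

    return PhantomCase(
        spec=spec,
        geometry=geometry,
        prior_volume=prior_volume,
        reirradiation_volume=reirr_volume,
        prior_dose=prior_dose,
        true_field=true_field,
        true_rigid=rigid,
        prior_masks=prior_masks,
        reirradiation_masks=reirr_masks,
        change_log=change_log,
        bumps=[(b.center.copy(), b.radius, b.amplitude, b.direction.copy()) for b in bumps],
        intensity_at=prior_intensity,
        dose_at=dose_at,
        displacement_at=displacement_at,
    )


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write NIfTI volumes, masks, the true field, a change log and the
    case manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rio.save_volume(case.prior_volume, out / "prior_ct.nii.gz")
    rio.save_volume(case.reirradiation_volume, out / "reirr_ct.nii.gz")
    rio.save_volume(case.prior_dose, out / "prior_dose.nii.gz")
    rio.save_field(case.true_field, out / "true_field.nii.gz")
    oars = []
    for pm, rm in zip(case.prior_masks, case.reirradiation_masks):
        pp, rp = f"mask_prior_{pm.name}.nii.gz", f"mask_reirr_{rm.name}.nii.gz"
        rio.save_mask(pm, out / pp)
        rio.save_mask(rm, out / rp)
        oars.append(
            {
                "name": pm.name,
                "organ_class": pm.organ_class,
                "prior_mask": pp,
                "reirradiation_mask": rp,
            }
        )
    manifest = CaseManifest(
        case_id=f"phantom_seed{case.spec.seed}_{case.spec.scenario}",
        prior_volume="prior_ct.nii.gz",
        prior_dose="prior_dose.nii.gz",
        reirradiation_volume="reirr_ct.nii.gz",
        oars=oars,
    )
    rio.save_manifest(manifest, out / "manifest.json")
    (out / "change_log.txt").write_text("\n".join(case.change_log) + "\n")
    return out / "manifest.json"
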