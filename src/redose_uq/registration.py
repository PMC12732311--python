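"""Rigid pre-alignment and the multi-resolution deformable ensemble engine.

The deformable engine is a dense variational registration: at each pyramid
level it performs gradient ascent on

    E(u) = S(fixed, moving o (rigid o (id + u))) - w * R(u)

where ``S`` is CC or MI over voxels whose mapped point lands inside the
moving volume, and ``R`` is a quadratic first-difference smoothness penalty
on the displacement field.  The four knobs the ensemble varies — similarity
measure, number of resolution levels, regularisation weight, initial
Gaussian smoothing sigma — are exactly the configuration axes exposed by
:class:`RegistrationConfig`.

The engine is deliberately generic: registration ensembles, the
plausibility gate and the uncertainty statistics downstream do not depend
on which engine produced the fields, and :func:`run_ensemble` accepts any
callable with the :func:`deform_register` signature as a backend.

Everything here is deterministic — there is no random number generation in
the registration path, so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, optimize

from .grids import (
    DeformationField,
    GridGeometry,
    RigidTransform,
    VolumeGrid,
)
from .similarity import cc_value_and_force, mi_value_and_force

#: converts the ensemble's nominal regularisation weight (the 100/400 scale
#: a planning system exposes) to the internal penalty weight; fixed model
#: constant, see docs/methods.md
REG_WEIGHT_SCALE = 1e-4

BONE_THRESHOLD = 300.0  # HU-like; above soft tissue, below bone
BONE_WEIGHT = 10.0

#: Gaussian width (mm) applied to each displacement update — "fluid"
#: regularisation, fixed for all ensemble members (the variable
#: regularisation axis is the quadratic penalty weight, not this).  A
#: physical width means coarse levels smooth over few control points while
#: the native level gets the strong smoothing a single-resolution
#: registration needs to stay coherent.
FLUID_SIGMA_MM = 6.0


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegistrationConfig:
    """One ensemble member's parameter set.

    ``label`` follows the CC5-style shorthand: similarity measure plus the
    number of resolution levels, extended with weight/sigma suffixes when an
    ensemble varies those axes.
    """

    similarity: str = "CC"
    resolution_levels: int = 3
    regularisation_weight: float = 100.0
    smoothing_sigma: float = 1.0  # mm
    label: str = ""
    max_iterations: int = 100  # per level
    convergence_tol: float = 1e-4  # relative energy change
    mi_bins: int = 128
    #: minimum energy improvement for a level's solution to be kept; below
    #: it the level reverts to its initial field.  Histogram-based metrics
    #: in particular admit tiny spurious gains from resampling artefacts
    #: even on perfectly aligned images; this floor stops the optimiser
    #: from chasing them.
    min_level_gain: float = 2e-3

    def __post_init__(self) -> None:
        if self.similarity not in ("CC", "MI"):
            raise ValueError(f"similarity must be CC or MI, got {self.similarity!r}")
        if self.resolution_levels < 1:
            raise ValueError("resolution_levels must be >= 1")
        if self.regularisation_weight <= 0:
            raise ValueError("regularisation_weight must be positive")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be non-negative")
        if not self.label:
            object.__setattr__(self, "label", f"{self.similarity}{self.resolution_levels}")


@dataclass
class RegistrationResult:
    config: RegistrationConfig
    field: DeformationField  # composed: rigid applied after the deformation
    rigid: RigidTransform
    diagnostics: dict = dc_field(default_factory=dict)


# -- ensemble grids ---------------------------------------------------------

#: similarity x {1,3,5} resolution levels, other knobs at defaults
SIX_GRID: dict[str, list] = {
    "similarity": ["CC", "MI"],
    "resolution_levels": [1, 3, 5],
}

#: similarity x {3,5} levels x regularisation weight {100,400} x sigma {1,2}
SIXTEEN_GRID: dict[str, list] = {
    "similarity": ["CC", "MI"],
    "resolution_levels": [3, 5],
    "regularisation_weight": [100.0, 400.0],
    "smoothing_sigma": [1.0, 2.0],
}

_GRID_AXES = ("similarity", "resolution_levels", "regularisation_weight", "smoothing_sigma")


def enumerate_ensemble(grid: dict[str, Sequence]) -> list[RegistrationConfig]:
    """Cartesian product of the parameter grid in deterministic order
    (similarity outermost, then levels, weight, sigma) with auto labels."""
    unknown = set(grid) - set(_GRID_AXES)
    if unknown:
        raise ValueError(f"unknown ensemble parameters: {sorted(unknown)}")
    for name, values in grid.items():
        if len(values) < 1:
            raise ValueError(f"parameter {name!r} has no values")
    defaults = RegistrationConfig()
    axes = {
        name: list(grid.get(name, [getattr(defaults, name)])) for name in _GRID_AXES
    }
    configs = []
    for sim, lev, w, sig in product(*(axes[a] for a in _GRID_AXES)):
        label = f"{sim}{lev}"
        if len(axes["regularisation_weight"]) > 1:
            label += f"_w{w:g}"
        if len(axes["smoothing_sigma"]) > 1:
            label += f"_s{sig:g}"
        configs.append(
            RegistrationConfig(
                similarity=sim,
                resolution_levels=int(lev),
                regularisation_weight=float(w),
                smoothing_sigma=float(sig),
                label=label,
            )
        )
    return configs


# -- rigid pre-alignment ----------------------------------------------------


def _smooth_mm(values: np.ndarray, sigma_mm: float, spacing) -> np.ndarray:
    if sigma_mm <= 0:
        return values
    return ndimage.gaussian_filter(values, sigma=[sigma_mm / s for s in spacing])


def _weighted_cc(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    am = np.sum(w * a) / wsum
    bm = np.sum(w * b) / wsum
    cov = np.sum(w * (a - am) * (b - bm)) / wsum
    va = np.sum(w * (a - am) ** 2) / wsum
    vb = np.sum(w * (b - bm) ** 2) / wsum
    if va < 1e-12 or vb < 1e-12:
        return 0.0
    return float(cov / np.sqrt(va * vb))


def rigid_register(
    reference: VolumeGrid,
    moving: VolumeGrid,
    bone_threshold: float = BONE_THRESHOLD,
    bone_weight: float = BONE_WEIGHT,
    stride: int = 2,
) -> RigidTransform:
    """6-DOF intensity registration with bone emphasis.

    High-intensity voxels (above ``bone_threshold``) are up-weighted in the
    correlation objective, so the alignment locks onto skeletal anatomy.
    Deterministic: centroid initialisation, a fixed multi-start grid of
    rotation offsets, then a Powell refinement; no randomness.
    """
    if np.std(reference.values) == 0 or np.std(moving.values) == 0:
        raise RegistrationError("flat image: rigid registration undefined")

    center = tuple(np.mean(np.stack(reference.geometry.extent_mm()), axis=0))

    def centroid(vol: VolumeGrid) -> np.ndarray:
        m = vol.values > bone_threshold
        if not np.any(m):
            m = np.ones_like(vol.values, dtype=bool)
        idx = np.argwhere(m)
        w = vol.values[m]
        w = w - w.min() + 1.0
        com_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
        return vol.geometry.to_physical(com_idx)

    t0 = centroid(moving) - centroid(reference)

    sl = (slice(None, None, stride),) * 3
    ref_sub = reference.values[sl]
    centers = reference.geometry.voxel_centers()[sl].reshape(-1, 3)
    ref_flat = ref_sub.ravel()
    weights = 1.0 + (bone_weight - 1.0) * (ref_flat > bone_threshold)
    n_mov = np.asarray(moving.geometry.size)

    def objective(params: np.ndarray) -> float:
        rot = tuple(np.deg2rad(params[:3]))
        t = tuple(params[3:])
        tr = RigidTransform(rot, t, center)
        idx = moving.geometry.to_index(tr.apply(centers))
        valid = np.all((idx >= 0) & (idx <= n_mov - 1), axis=1)
        if valid.sum() < 0.05 * valid.size:
            return 2.0
        vals = ndimage.map_coordinates(
            moving.values, idx[valid].T, order=1, mode="nearest", prefilter=False
        )
        return -_weighted_cc(ref_flat[valid], vals, weights[valid])

    # fixed multi-start over single-axis rotation offsets
    starts = [np.zeros(3)]
    for axis in range(3):
        for sign in (-1.0, 1.0):
            off = np.zeros(3)
            off[axis] = 3.0 * sign
            starts.append(off)
    best = None
    for rot0 in starts:
        p = np.concatenate([rot0, t0])
        val = objective(p)
        if best is None or val < best[0]:
            best = (val, p)
    if best[0] >= 1.5:
        raise RegistrationError("no usable overlap between reference and moving volumes")

    res = optimize.minimize(
        objective,
        best[1],
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 2000},
    )
    params = res.x
    return RigidTransform(
        rotation=tuple(np.deg2rad(params[:3])),
        translation=tuple(float(v) for v in params[3:]),
        center=center,
    )


# -- deformable engine ------------------------------------------------------


def _level_geometry(geometry: GridGeometry, factor: int) -> GridGeometry:
    if factor == 1:
        return geometry
    size = tuple(max(2, (n - 1) // factor + 1) for n in geometry.size)
    spacing = tuple(s * factor for s in geometry.spacing)
    return GridGeometry(geometry.origin, spacing, size)


def _resample_clamped(values: np.ndarray, src: GridGeometry, tgt: GridGeometry) -> np.ndarray:
    """Linear resampling with edge clamping (for pyramid transfers)."""
    idx = src.to_index(tgt.voxel_centers().reshape(-1, 3))
    out = ndimage.map_coordinates(values, idx.T, order=1, mode="nearest", prefilter=False)
    return out.reshape(tgt.size)


#: weight of the displacement-magnitude (Tikhonov) term inside the
#: regularisation penalty, per mm^2.  A pure first-difference penalty is
#: translation-invariant, so an arbitrarily large weight would still admit
#: uniform drift; the magnitude term anchors the high-weight limit at zero
#: displacement (i.e., at the rigid pre-alignment).
PENALTY_MAGNITUDE_WEIGHT = 1e-3


def _penalty_and_grad(u: np.ndarray, spacing) -> tuple[float, np.ndarray]:
    """Smoothness penalty (mean squared first difference, per mm, plus a
    small displacement-magnitude term) and its exact gradient."""
    total = 0.0
    grad = np.zeros_like(u)
    count = 0
    for a in range(3):
        h = spacing[a]
        d = np.diff(u, axis=a) / h
        total += float(np.sum(d * d))
        count += d.size
        g = 2.0 * d / h
        front = [slice(None)] * 4
        back = [slice(None)] * 4
        front[a] = slice(0, -1)
        back[a] = slice(1, None)
        grad[tuple(front)] -= g
        grad[tuple(back)] += g
    if count == 0:
        count = 1
    total /= count
    grad /= count
    mag = PENALTY_MAGNITUDE_WEIGHT
    total += mag * float(np.mean(u * u))
    grad += mag * 2.0 * u / u.size
    return total, grad


def deform_register(
    reference: VolumeGrid,
    moving: VolumeGrid,
    rigid: RigidTransform,
    config: RegistrationConfig,
    jacobian_floor: float = 0.0,
) -> RegistrationResult:
    """Dense multi-resolution deformable registration.

    Both images receive the config's initial Gaussian smoothing (mm) before
    the coarsest level.  The pyramid halves the *displacement-grid*
    resolution per level (finest level on the native reference grid) and
    applies matching Gaussian image smoothing, but the similarity measure
    is always evaluated over the full native sampling of the reference
    grid: a histogram measure estimated from a few thousand coarse-level
    samples is dominated by estimator bias, and drifts even on identical
    images.  Returns the composed field mapping reference points into the
    prior (moving) frame: the estimated deformation followed by the rigid
    pre-alignment.
    """
    ref_geom = reference.geometry
    fix0 = _smooth_mm(reference.values, config.smoothing_sigma, ref_geom.spacing)
    mov0 = _smooth_mm(moving.values, config.smoothing_sigma, moving.geometry.spacing)

    levels = config.resolution_levels
    # factor-2 pyramid; the coarsest displacement grid is capped so no axis
    # drops below ~8 control points, and duplicate factors arising from the
    # cap are merged
    max_factor = 1
    while min(ref_geom.size) // (2 * max_factor) >= 8:
        max_factor *= 2
    factors = sorted(
        {min(2 ** (levels - 1 - l), max_factor) for l in range(levels)}, reverse=True
    )

    u = None
    u_geom = None
    diagnostics: dict = {"levels": [], "factors": factors}
    for factor in factors:
        geom_l = _level_geometry(ref_geom, factor)
        aa_sigma = 0.5 * factor if factor > 1 else 0.0  # scale-matched smoothing, voxels
        fix_l = ndimage.gaussian_filter(fix0, aa_sigma) if aa_sigma else fix0
        mov_l = ndimage.gaussian_filter(mov0, aa_sigma) if aa_sigma else mov0
        mov_grad = np.stack(np.gradient(mov_l, *moving.geometry.spacing), axis=-1)
        if u is None:
            u = np.zeros(geom_l.size + (3,))
        else:
            u = np.stack(
                [_resample_clamped(u[..., c], u_geom, geom_l) for c in range(3)], axis=-1
            )
        u_geom = geom_l
        u, level_diag = _optimise_level(
            fix_l, ref_geom, geom_l, factor, mov_l, mov_grad, moving.geometry, rigid, u, config
        )
        level_diag["factor"] = factor
        diagnostics["levels"].append(level_diag)

    u_native = _upsample_field(u, u_geom, ref_geom)
    deformation = DeformationField(ref_geom, u_native)
    composed = deformation.compose_rigid(rigid)
    min_jac = float(composed.jacobian_determinant().min())
    diagnostics["min_jacobian"] = min_jac
    diagnostics["folded"] = bool(min_jac <= jacobian_floor)
    diagnostics["converged"] = all(d["converged"] for d in diagnostics["levels"])
    diagnostics["final_similarity"] = diagnostics["levels"][-1]["similarity"]
    return RegistrationResult(config=config, field=composed, rigid=rigid, diagnostics=diagnostics)


def _upsample_field(u: np.ndarray, src: GridGeometry, tgt: GridGeometry) -> np.ndarray:
    if src == tgt:
        return u
    return np.stack([_resample_clamped(u[..., c], src, tgt) for c in range(3)], axis=-1)


def _optimise_level(
    fix_vals: np.ndarray,
    ref_geom: GridGeometry,
    level_geom: GridGeometry,
    factor: int,
    mov_vals: np.ndarray,
    mov_grad: np.ndarray,
    mov_geom: GridGeometry,
    rigid: RigidTransform,
    u: np.ndarray,
    config: RegistrationConfig,
) -> tuple[np.ndarray, dict]:
    """Ascent on E(u) = S(u) - w * R(u) for one pyramid level.

    ``u`` lives on the level's (possibly coarser) grid; the similarity is
    evaluated at every native reference voxel center with ``u`` linearly
    upsampled, and the native force field is projected back onto the level
    grid (smoothing + sampling, the approximate adjoint of the
    upsampling).  The smoothness penalty acts on the level-grid field.
    """
    centers = ref_geom.voxel_centers().reshape(-1, 3)
    fix_flat = fix_vals.ravel()
    n_mov = np.asarray(mov_geom.size)
    Rmat = rigid.matrix()
    w_eff = config.regularisation_weight * REG_WEIGHT_SCALE
    spacing = level_geom.spacing
    max_step = min(0.4 * min(spacing), 2.0 * min(mov_geom.spacing))
    fluid_sigma = max(1.0, FLUID_SIGMA_MM / min(spacing))
    mi_bins = min(config.mi_bins, max(8, int(np.sqrt(fix_flat.size / 4.0))))
    # histogram bin edges frozen per level: a dense field could otherwise
    # raise the metric by shrinking the sampled intensity range
    fix_range = (float(fix_vals.min()), float(fix_vals.max()))
    mov_range = (float(mov_vals.min()), float(mov_vals.max()))

    def to_native(u_arr: np.ndarray) -> np.ndarray:
        return _upsample_field(u_arr, level_geom, ref_geom).reshape(-1, 3)

    def valid_subset(u_native: np.ndarray) -> np.ndarray:
        idx = mov_geom.to_index(rigid.apply(centers + u_native))
        return np.all((idx >= 0) & (idx <= n_mov - 1), axis=1)

    def similarity(u_native: np.ndarray, subset: np.ndarray, with_force: bool):
        """Similarity over a frozen native-voxel subset.

        The subset (voxels mapping inside the moving extent) is fixed per
        outer iteration: re-deriving it at every line-search trial would
        make the energy discontinuous whenever a boundary voxel crosses
        the extent, swamping genuine metric changes.  Samples drifting
        marginally outside during a trial are edge-clamped.
        """
        idx = mov_geom.to_index(rigid.apply(centers[subset] + u_native[subset]))
        mv = ndimage.map_coordinates(
            mov_vals, idx.T, order=1, mode="nearest", prefilter=False
        )
        fv = fix_flat[subset]
        if config.similarity == "CC":
            value, force = cc_value_and_force(fv, mv) if with_force else (
                _cc_only(fv, mv), None)
        else:
            value, force = mi_value_and_force(fv, mv, mi_bins, fix_range, mov_range)
            if not with_force:
                force = None
        if not with_force:
            return value, None
        g = np.stack(
            [
                ndimage.map_coordinates(
                    mov_grad[..., c], idx.T, order=1, mode="nearest", prefilter=False
                )
                for c in range(3)
            ],
            axis=-1,
        )
        g_ref = g @ Rmat  # chain rule through the rigid map: R^T grad
        force_native = np.zeros((centers.shape[0], 3))
        force_native[subset] = force[:, None] * g_ref
        return value, force_native.reshape(ref_geom.size + (3,))

    def project(force_native: np.ndarray) -> np.ndarray:
        """Approximate adjoint of the coarse->native upsampling."""
        if factor == 1:
            return force_native
        out = np.empty(level_geom.size + (3,))
        for c in range(3):
            sm = ndimage.gaussian_filter(force_native[..., c], 0.5 * factor)
            out[..., c] = _resample_clamped(sm, ref_geom, level_geom)
        return out

    converged = False
    iterations = 0
    E = None
    E_init = None
    u_init = u.copy()
    final_sim = float("nan")
    cap_frac = 0.05  # voxels with >=5% of the max gradient move at full step
    for it in range(config.max_iterations):
        iterations = it + 1
        un = to_native(u)
        subset = valid_subset(un)
        if subset.sum() < 8:
            raise RegistrationError("mapped volume leaves the moving extent")
        sim, force_native = similarity(un, subset, with_force=True)
        final_sim = sim
        pen, pen_grad = _penalty_and_grad(u, spacing)
        E = sim - w_eff * pen
        if E_init is None:
            E_init = E
        G = project(force_native) - w_eff * pen_grad
        gmag = np.linalg.norm(G, axis=-1, keepdims=True)
        gmax = float(gmag.max())
        if gmax < 1e-14:
            converged = True
            break
        # cap-normalised direction: a positive diagonal scaling of the
        # gradient (hence still an ascent direction), flattening the huge
        # dynamic range between bone-edge and soft-tissue forces
        D = G / np.maximum(gmag, cap_frac * gmax)
        # fluid-like smoothing of the update keeps neighbouring control
        # points moving together; without it a dense MI flow can raise the
        # metric by rearranging individual voxels (histogram over-fitting)
        for c in range(3):
            D[..., c] = ndimage.gaussian_filter(D[..., c], fluid_sigma)
        tau = max_step
        accepted = False
        for _ in range(10):
            u_try = u + tau * D
            s_try, _ = similarity(to_native(u_try), subset, with_force=False)
            p_try, _ = _penalty_and_grad(u_try, spacing)
            E_try = s_try - w_eff * p_try
            if E_try > E:
                accepted = True
                break
            tau *= 0.5
        if not accepted:
            converged = True  # no ascent direction at this resolution
            break
        rel = abs(E_try - E) / (abs(E) + 1e-12)
        u, E = u_try, E_try
        final_sim = s_try
        if rel < config.convergence_tol:
            converged = True
            break
    reverted = False
    if E is None or E_init is None or (E - E_init) < config.min_level_gain:
        # gains below the noise floor of the metric: keep the initial field
        u = u_init
        reverted = E is not None
    return u, {
        "similarity": float(final_sim),
        "iterations": iterations,
        "converged": converged,
        "reverted": reverted,
        "energy": float(E) if E is not None else float("nan"),
    }


def _cc_only(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def run_ensemble(
    reference: VolumeGrid,
    moving: VolumeGrid,
    configs: Sequence[RegistrationConfig],
    rigid: RigidTransform | None = None,
    engine: Callable[..., RegistrationResult] = deform_register,
) -> list[RegistrationResult]:
    """Run every ensemble member against one shared rigid pre-alignment.

    A member's failure is recorded in its diagnostics (with a zero
    deformation falling back to the rigid mapping); the ensemble always
    completes, in config order.
    """
    if not configs:
        raise ValueError("empty ensemble")
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("ensemble labels must be unique")
    if rigid is None:
        rigid = rigid_register(reference, moving)
    results = []
    for config in configs:
        try:
            results.append(engine(reference, moving, rigid, config))
        except Exception as exc:  # member failure must not kill the ensemble
            fallback = DeformationField.zero(reference.geometry).compose_rigid(rigid)
            results.append(
                RegistrationResult(
                    config=config,
                    field=fallback,
                    rigid=rigid,
                    diagnostics={"error": f"{type(exc).__name__}: {exc}", "converged": False},
                )
            )
    return results
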