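# Methods

`redose-uq` estimates how much a mapped prior-course dose depends on the
deformable image registration (DIR) that produced it. The method is an
ensemble-with-a-gate: run several DIRs that differ only in their
configuration, keep — *per organ at risk* — the ones that are locally
geometrically plausible, map the prior dose through each survivor, and
report the spread.

## Pipeline

For one case (a prior planning scan with its dose and OAR contours, and a
reirradiation planning scan with its own contours, the reirradiation scan
being the reference frame):

1. **Rigid pre-alignment.** One intensity-based 6-DOF registration shared
   by the whole ensemble, with voxels above a bone threshold (300 HU-like
   units) up-weighted 10:1 so the alignment locks onto skeletal anatomy.
   Deterministic: bone-centroid initialisation, a fixed grid of rotation
   starts, Powell refinement.
2. **Deformable ensemble.** Dense multi-resolution variational DIRs over
   the four configuration axes: similarity (CC or MI), resolution levels
   (1, 3, 5), regularisation weight (100, 400), initial Gaussian smoothing
   sigma (1, 2 mm). The standard grids are `six` (CC/MI x 1/3/5 levels)
   and `sixteen` (CC/MI x 3/5 levels x weight 100/400 x sigma 1/2 mm).
3. **Local plausibility gate.** Each prior-scan OAR contour is warped
   through each DIR and compared with the reirradiation-scan contour using
   the mean distance to agreement (mDTA, symmetric mean surface distance).
   A DIR passes for an OAR iff mDTA <= 0.3 cm (the TG-132 tolerance,
   inclusive). The same DIR can pass for one organ and fail for its
   neighbour; that locality is the point.
4. **Dose mapping.** Pull-back with trilinear interpolation: mapped dose
   at a reference voxel is the prior dose sampled at the voxel's mapped
   point. Interpolation, not energy transport — integral dose is not
   conserved under a non-rigid map, and nothing downstream assumes it is.
   Voxels mapping outside the prior dose grid are marked invalid and
   excluded from all statistics (silent zeros would bias mean doses low).
   Dose is mapped once per DIR and the per-OAR gate selects which mapped
   doses enter each organ's statistics.
5. **Uncertainty products.** Per OAR, over the plausible subset: mean and
   sample SD (n-1) of the class-appropriate DVH metric — D0.1cm3 for
   serial organs, mean dose for parallel organs; the ensemble of
   cumulative DVH curves (default bin width 0.1 Gy, relative volumes,
   restricted to valid in-mask voxels); and the voxel-wise SD map of
   mapped dose inside the organ as delineated on the reirradiation scan.
   Cohort reporting aggregates plausibility percentages by case and organ
   and summarises metric-SD distributions with box-plot statistics
   (1.5 x IQR outlier rule).

An ensemble of one plausible member reports its mean with the SD flagged
undefined — never 0, which would fake certainty. An organ with zero
plausible members is reported "not mappable" rather than with numbers.

## The registration engine

The proprietary algorithm behind the published configuration axes is not
available; the engine here is a generic dense multi-resolution variational
registration exposing the same four knobs. The ensemble/gate/statistics
machinery is engine-agnostic — `run_ensemble` accepts any backend with the
`deform_register` signature — and no numerical parity with any commercial
system is claimed.

Each pyramid level performs ascent on

    E(u) = S(fixed, moving o (rigid o (id + u))) − w_eff * R(u)

* `S` is the similarity. CC is the Pearson correlation over valid voxels.
  The "MI" axis is driven by Studholme's normalised mutual information
  (NMI) computed from a Parzen-smoothed (sigma 1 bin) tent-kernel joint
  histogram with 128 bins and *frozen* bin edges per level. Each hardening
  matters because a dense displacement field — unlike a low-dimensional
  parametric transform — can exploit every weakness of a histogram
  estimator voxel by voxel: adaptive bin edges reward shrinking the
  sampled intensity range, raw tent histograms reward sliding intensities
  onto the bin lattice, and plain MI rewards the marginal-entropy drop
  that off-lattice interpolation produces. Each failure mode was
  diagnosed on identity phantoms (where any field growth is spurious) and
  removed structurally rather than by iteration limits. 128 bins rather
  than the conventional 32 because the phantoms put ±50 HU of soft-tissue
  contrast inside a 1300 HU total range; 32 equal-width bins cannot
  resolve it.
* `R(u)` is a quadratic first-difference smoothness penalty (mean squared
  displacement gradient, per mm) plus a small displacement-magnitude
  (Tikhonov) term (1e-3 / mm^2). The magnitude term exists because a pure
  first-difference penalty is translation-invariant: without it, an
  arbitrarily large weight still admits uniform drift, and the weight
  axis would not monotonically shrink the field.
* `w_eff = weight x 1e-4` maps the ensemble's nominal weights (the
  100/400 scale a planning system exposes) onto the penalty scale at
  which 100–400 permits recovery of ~6 mm deformations while 1e6
  suppresses the field.
* The similarity is always evaluated over the full native sampling of the
  reference grid; pyramid levels control the *displacement-grid*
  resolution (factor-2 per level, finest = native, coarsest capped at ~8
  control points per axis) and add scale-matched image smoothing. A
  histogram metric estimated from a few thousand coarse-level samples is
  dominated by estimator bias and drifts even on identical images.
* The update direction is the energy gradient under a positive diagonal
  rescaling (per-voxel cap-normalisation at 5% of the max gradient
  magnitude) followed by a fixed 6 mm Gaussian "fluid" smoothing. The
  rescaling is needed because bone-edge voxels carry ~1e4 times the raw
  force of soft tissue, which stalls plain gradient ascent; both
  operations preserve the ascent property, and a backtracking line search
  on `E` (initial step 0.4 level voxels, capped at 2 native voxels)
  guards every step. Iterations cap at 100 per level with a 1e-4
  relative-change stopping tolerance.
* A level's solution is kept only if it improved `E` by at least 2e-3
  (`min_level_gain`); otherwise the level reverts to its initial field.
  This is the floor below which observed gains are estimator artefact
  rather than alignment: it makes registration of identical images return
  an exactly zero field, which in turn makes the zero-uncertainty limit
  (identical ensemble -> SD exactly 0) hold exactly.

There is no randomness anywhere in the registration path; repeated runs
are bit-identical.

## mDTA conventions

mDTA is the symmetric mean surface distance: the mean, over the union of
both voxelised surfaces' point sets, of the Euclidean distance to the
other surface (directions therefore weighted by their surface-point
counts). Surfaces are 6-connected boundary voxels (out-of-grid counts as
background); distances come from a Euclidean distance transform with
physical spacing; results are reported in cm. Warped masks threshold
linearly-interpolated occupancy at 0.5. Empty or vanished masks yield
"implausible, reason coded" — distinct from a large distance, so
anatomical absence is not conflated with misalignment. Whether a clinical
system's mDTA is directed or symmetric is generally unspecified; the
directed variants are one-line changes behind the `mdta` function.

## The phantom module

No clinical data ships with the package; every study condition is a
synthetic case with analytic ground truth:

* **Intensity model** (arbitrary HU-like units, fixed ranges): a seeded
  sum of low-frequency cosines for background (−50..50), smooth-edged
  soft-tissue organs (20..120), three non-collinear high-intensity bone
  spheres (700..1200) for the rigid stage to lock onto. Everything is a
  closed-form function of position, so the reirradiation scan is the prior
  intensity evaluated *exactly* at deformed points — no interpolation
  error enters the ground truth.
* **Deformation**: a compact-support displacement bump with a flat core
  and a C2 quintic taper; peak displacement equals the requested
  amplitude, the support radius scales with amplitude so the map stays
  diffeomorphic (checked on the grid; folding specs are rejected). The
  deformable component is damped to zero in a C2 shell around each bone
  landmark — bone is rigid anatomy, and a rigid pre-alignment on
  deformed bone would be ill-posed.
* **Dose**: a sum of anisotropic Gaussian blobs with seeded parameters,
  retained in closed form as the pull-back oracle.
* **Scenarios**: `identity`, `rigid_offset` (known 6-DOF offset),
  `smooth_deformation`, and `tissue_disappearance` — the last replaces
  one organ's image region with background intensity on the
  reirradiation scan and shrinks its contour to a small remnant,
  emulating response/resection between courses, the failure mode the
  local gate exists to catch. Organs disjoint from the ablation are
  bit-identical to the smooth-deformation case at the same seed.
* Default grid 64^3 at 1.5 mm isotropic; a clinical-aspect preset uses
  0.8 x 0.8 x 2.5 mm voxels. Default layout: a focal organ inside the
  deformation/ablation region, a distant organ well away from it, and a
  serial tube ("cord"-like). One seeded generator per case with a frozen
  draw order.

What the phantoms do *not* emulate: CT texture and noise, intensity
calibration differences between scans, respiratory motion, oblique
geometries, truncated fields of view, and contour inter-observer
variability. Passing phantom suites therefore demonstrates the machinery
(geometry, gating, statistics, determinism) and the engine's behaviour
under controlled deformation — not clinical registration accuracy.

## Problem sizes and verification

The bundled verification suites use: identity, 64^3 at 1.5 mm (every
ensemble member must stay below a quarter voxel of mean displacement,
every OAR plausible, both uncertainty products exactly zero); recovery,
64^3 at 1.5 mm with 6 mm amplitude (every first-grid member must beat the
zero field against the analytic truth; dose pull-back within 0.5% of peak
against the closed form); locality, 48^3 at 2 mm with 2 mm amplitude and
an ablated focal organ (ablated organ fails the gate for at least one
member, distant organ passes for all). Unit suites cross-check mDTA
against brute-force nearest-neighbour search, voxel-wise SD against a
naive two-pass recomputation, resampling against SimpleITK, and the DVH
against its analytic CDF.

## Known limitations

* The engine's recovery of a 6 mm deformation is partial (mean endpoint
  error typically drops by 10–30% depending on configuration); the
  method's products quantify *ensemble spread among plausible members*,
  not registration truth error.
* Equieffective-dose conversion (EQD2/BED) and multi-course summation are
  out of scope: mapped dose is physical dose.
* Pull-back dose mapping is the convention of clinical "deform dose"
  tools; energy/mass-conserving mapping is a separate research topic.
* Axis-aligned geometry only; DICOM import/export is not provided (NIfTI
  plus a JSON case manifest are the interchange formats).
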