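"""Intensity similarity measures and their voxel-wise derivatives.

Two measures drive the deformable engine, matching the two the registration
ensemble varies: Pearson correlation coefficient (CC) and mutual
information (MI).  For each we provide the scalar value and the derivative
of the value with respect to each moving-image sample — the "force" that,
multiplied by the warped moving-image gradient, becomes the displacement
update direction.

The public :func:`compute_mi` metric uses a plain equal-width joint
histogram.  The engine's internal MI uses a tent-kernel (partial-volume)
histogram over the moving axis so the derivative is well defined; the two
agree in the many-sample limit.
"""

from __future__ import annotations

import numpy as np

DEFAULT_MI_BINS = 32  # reported metric; the engine's internal default is finer


def compute_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length sample vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("sample vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance samples have undefined correlation")
    return float(np.corrcoef(a, b)[0, 1])


def cc_value_and_force(fixed: np.ndarray, moving: np.ndarray) -> tuple[float, np.ndarray]:
    """CC and d(CC)/d(moving sample) per sample."""
    f = np.asarray(fixed, dtype=float).ravel()
    m = np.asarray(moving, dtype=float).ravel()
    n = f.size
    fc = f - f.mean()
    mc = m - m.mean()
    sf = np.sqrt(np.mean(fc * fc))
    sm = np.sqrt(np.mean(mc * mc))
    if sf < 1e-12 or sm < 1e-12:
        return 0.0, np.zeros_like(m)
    cc = float(np.mean(fc * mc) / (sf * sm))
    force = (fc / (sf * sm) - cc * mc / (sm * sm)) / n
    return cc, force


def compute_mi(a: np.ndarray, b: np.ndarray, bins: int = DEFAULT_MI_BINS) -> float:
    """Mutual information (nats) of the joint equal-width histogram.

    Bin edges span each sample's observed range; a degenerate (constant)
    sample collapses to a single bin and yields 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("sample vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two samples")
    if bins < 2:
        raise ValueError("need at least two bins")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    return _mi_from_joint(joint / joint.sum())


def _mi_from_joint(p: np.ndarray) -> float:
    pi = p.sum(axis=1, keepdims=True)
    qj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pi * qj))
    return float(np.nansum(terms))


def entropy(a: np.ndarray, bins: int = DEFAULT_MI_BINS) -> float:
    """Shannon entropy (nats) of the equal-width marginal histogram."""
    hist, _ = np.histogram(np.asarray(a).ravel(), bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


#: Parzen smoothing of the joint histogram, in bins
MI_PARZEN_SIGMA = 1.0


def mi_value_and_force(
    fixed: np.ndarray,
    moving: np.ndarray,
    bins: int = DEFAULT_MI_BINS,
    fixed_range: tuple[float, float] | None = None,
    moving_range: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Normalised-MI driving value and d(value)/d(moving sample).

    The estimator the engine climbs is Studholme's normalised mutual
    information, NMI = (H(f) + H(m)) / H(f, m), computed from a
    Parzen-smoothed joint histogram with *fixed* bin edges.  Three
    hardening measures matter for a dense displacement field, which —
    unlike a low-dimensional parametric transform — can attack every
    weakness of a histogram estimator voxel by voxel:

    * tent-kernel accumulation over the moving axis makes the histogram
      differentiable in the moving intensities;
    * Gaussian Parzen smoothing of the accumulated histogram removes the
      reward for sliding intensities onto the bin lattice;
    * frozen bin edges (pass ``fixed_range``/``moving_range``) remove the
      reward for shrinking the sampled intensity range, and the entropy
      normalisation in NMI removes the reward for blurring the moving
      samples through off-lattice interpolation.

    Fixed samples are hard-binned; the derivative follows the tent weights
    (+/- 1/binwidth) through the Parzen blur by convolving the
    dValue/d(bin) matrix with the same kernel.
    """
    from scipy import ndimage

    f = np.asarray(fixed, dtype=float).ravel()
    m = np.asarray(moving, dtype=float).ravel()
    n = f.size
    f_lo, f_hi = fixed_range if fixed_range is not None else (f.min(), f.max())
    m_lo, m_hi = moving_range if moving_range is not None else (m.min(), m.max())
    if f_hi <= f_lo or m_hi <= m_lo:
        return 0.0, np.zeros_like(m)

    fi = np.clip(((f - f_lo) / (f_hi - f_lo) * bins).astype(int), 0, bins - 1)
    m_width = (m_hi - m_lo) / (bins - 1)
    pos = np.clip((m - m_lo) / m_width, 0.0, bins - 1.0)
    j0 = np.clip(pos.astype(int), 0, bins - 2)
    frac = np.clip(pos - j0, 0.0, 1.0)

    joint = np.zeros((bins, bins))
    np.add.at(joint, (fi, j0), 1.0 - frac)
    np.add.at(joint, (fi, j0 + 1), frac)
    joint = ndimage.gaussian_filter(joint, MI_PARZEN_SIGMA, mode="constant")
    p = np.maximum(joint / joint.sum(), 1e-12)
    p /= p.sum()
    pi = p.sum(axis=1, keepdims=True)
    qj = p.sum(axis=0, keepdims=True)
    h_f = float(-np.sum(pi * np.log(pi)))
    h_m = float(-np.sum(qj * np.log(qj)))
    h_fm = float(-np.sum(p * np.log(p)))
    value = (h_f + h_m) / h_fm

    # dNMI/dp_ij assembled from dH/dp of the three entropies
    L = (value * (1.0 + np.log(p)) - 2.0 - np.log(pi * qj)) / h_fm
    # chain rule through the Parzen blur: dNMI/d(raw count)_ij = (K * L)_ij
    Lb = ndimage.gaussian_filter(L, MI_PARZEN_SIGMA, mode="constant")
    # d(value)/dm_k = sum_j dw_j/dm * Lb(i_k, j) / n;  dw/dm = -/+ 1/width
    force = (Lb[fi, j0 + 1] - Lb[fi, j0]) / (n * m_width)
    return value, force
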