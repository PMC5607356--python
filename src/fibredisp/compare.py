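"""FOD reorientation under deformation fields and cross-modality statistics.

Deformation fields (from an external deformable registration) are consumed,
not estimated. For each grid point the local affine is the Jacobian of the
mapping; its polar-decomposition rotation reorients the FODs so fibre
orientations stay attached to the bulk anatomy. Comparison statistics
follow the region / left-right-profile / voxel hierarchy: ROI means,
corpus-callosum dispersion profiles, Pearson correlations (optionally on a
low-ODI subset), per-patch FOD amplitude correlations, and an OLS
regression of the dMRI profile on the myelin and astrocyte profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fod import AxialFOD2D

__all__ = [
    "DeformationField2D",
    "ProfileResult",
    "local_rotations",
    "reorient_fod",
    "roi_mean",
    "cc_profile",
    "correlate_profiles",
    "fod_correlation_map",
    "profile_regression",
]


@dataclass
class DeformationField2D:
    """Per-grid-point displacement (pixels) mapping moving -> fixed space.

    ``displacement``: (H, W, 2) array ordered (row, col), i.e. a point at
    (r, c) maps to (r, c) + displacement[r, c].
    """

    displacement: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.displacement, dtype=float)
        if d.ndim != 3 or d.shape[-1] != 2:
            raise ValueError("displacement must be (H, W, 2)")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacement must be finite")
        self.displacement = d


@dataclass
class ProfileResult:
    """Left-right dispersion profile: mean ODI per position along a tract."""

    positions: np.ndarray
    odi_mean: np.ndarray
    n_voxels: np.ndarray


def local_rotations(field: DeformationField2D):
    """Rotation angle (degrees) of the local affine at each grid point.

    The Jacobian of the mapping x -> x + u(x) is estimated by central
    differences and its rotation extracted by polar decomposition. Points
    with non-positive Jacobian determinant (folding) are NaN with a warning.
    Edge rows/columns use one-sided differences.

    Angles follow the package convention: counter-clockwise in the displayed
    image (+x = columns, +y = up).
    """
    u = field.displacement
    # gradient axis 0 = rows (displayed -y), axis 1 = cols (+x)
    dur_dr, dur_dc = np.gradient(u[..., 0])
    duc_dr, duc_dc = np.gradient(u[..., 1])
    # express in (x, y-up): x = c, y = -r
    # ux = uc, uy = -ur; d/dx = d/dc, d/dy = -d/dr
    j11 = 1.0 + duc_dc          # dTx/dx
    j12 = -duc_dr               # dTx/dy
    j21 = -dur_dc               # dTy/dx
    j22 = 1.0 + dur_dr          # dTy/dy

    det = j11 * j22 - j12 * j21
    bad = det <= 0
    if bad.any():
        warnings.warn(
            f"{bad.sum()} grid points have non-positive Jacobian determinant "
            "(folding); rotations masked there", RuntimeWarning, stacklevel=2)

    # polar decomposition rotation of a 2x2 matrix J: R = J (J^T J)^{-1/2};
    # closed form: angle = atan2(j21 - j12, j11 + j22)
    angle = np.rad2deg(np.arctan2(j21 - j12, j11 + j22))
    return np.where(bad, np.nan, angle)


def reorient_fod(fod: AxialFOD2D, angle_deg: float) -> AxialFOD2D:
    """Rotate an FOD by ``angle_deg`` (mod 180) with linear bin interpolation.

    Mass is conserved exactly: the shift splits each bin's mass between the
    two covering destination bins.
    """
    shift = (angle_deg % 180.0) / fod.bin_width
    i = int(np.floor(shift))
    frac = shift - i
    mass = (1.0 - frac) * np.roll(fod.mass, i) + frac * np.roll(fod.mass, i + 1)
    return AxialFOD2D(fod.bin_edges, mass)


def roi_mean(odi_map, mask):
    """Mean ODI over non-missing masked voxels; returns (mean, count)."""
    m = np.asarray(odi_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != m.shape:
        raise ValueError("mask shape must match the map")
    vals = m[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("mask does not overlap any valid voxel")
    return float(vals.mean()), int(vals.size)


def cc_profile(odi_map, cc_mask, axis: int = 1, min_count: int = 2) -> ProfileResult:
    """Left-right dispersion profile of a masked structure.

    For each position along ``axis`` (default 1 = columns = left-right), the
    mean ODI over masked, non-missing voxels in the orthogonal direction(s).
    Positions with fewer than ``min_count`` voxels are dropped.
    """
    m = np.asarray(odi_map, dtype=float)
    mask = np.asarray(cc_mask, dtype=bool)
    if mask.shape != m.shape:
        raise ValueError("mask shape must match the map")
    m = np.where(mask & np.isfinite(m), m, np.nan)
    other = tuple(i for i in range(m.ndim) if i != axis)
    count = np.sum(np.isfinite(m), axis=other)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(m, axis=other)
    keep = count >= min_count
    return ProfileResult(positions=np.flatnonzero(keep),
                         odi_mean=mean[keep], n_voxels=count[keep])


def _as_series(p):
    if isinstance(p, ProfileResult):
        return p.positions, p.odi_mean
    a = np.asarray(p, dtype=float)
    return np.arange(a.size), a


def correlate_profiles(a, b, subset_max: float | None = None):
    """Pearson r between two profiles matched on position.

    Returns a dict with ``r`` (all pairs), ``n``, and — when ``subset_max``
    is given — ``r_subset``/``n_subset`` over pairs whose first-series value
    is below the cutoff (the low-dispersion regime). Zero-variance input
    yields NaN with ``degenerate=True``.
    """
    pa, va = _as_series(a)
    pb, vb = _as_series(b)
    common, ia, ib = np.intersect1d(pa, pb, return_indices=True)
    x, y = va[ia], vb[ib]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 matched positions")
    out = {"n": int(x.size)}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        out.update(r=np.nan, degenerate=True)
        return out
    out.update(r=float(stats.pearsonr(x, y).statistic), degenerate=False)
    if subset_max is not None:
        sel = x < subset_max
        out["n_subset"] = int(sel.sum())
        if sel.sum() >= 3 and np.ptp(x[sel]) > 0 and np.ptp(y[sel]) > 0:
            out["r_subset"] = float(stats.pearsonr(x[sel], y[sel]).statistic)
        else:
            out["r_subset"] = np.nan
    return out


def fod_correlation_map(fods_a, fods_b):
    """Per-patch Pearson r between FOD amplitude vectors over angle bins.

    Inputs are matching (rows, cols) object arrays of :class:`AxialFOD2D`
    (or None). Missing or zero-variance patches yield NaN.
    """
    fa = np.asarray(fods_a, dtype=object)
    fb = np.asarray(fods_b, dtype=object)
    if fa.shape != fb.shape:
        raise ValueError("patch grids must match")
    out = np.full(fa.shape, np.nan)
    for idx in np.ndindex(fa.shape):
        a, b = fa[idx], fb[idx]
        if a is None or b is None:
            continue
        if a.n_bins != b.n_bins:
            raise ValueError("angular grids must match")
        if np.ptp(a.mass) == 0 or np.ptp(b.mass) == 0:
            continue
        out[idx] = stats.pearsonr(a.mass, b.mass).statistic
    return out


def profile_regression(dmri_profile, myelin_profile, astro_profile):
    """OLS of the dMRI profile on the myelin and astrocyte profiles.

    Returns a dict with coefficients (intercept, myelin, astro), standard
    errors, 95% confidence intervals, R^2 and a collinearity flag
    (condition number > 1e8).
    """
    import statsmodels.api as sm

    _, y = _as_series(dmri_profile)
    _, xm = _as_series(myelin_profile)
    _, xa = _as_series(astro_profile)
    if not (y.size == xm.size == xa.size):
        raise ValueError("profiles must share positions")
    if y.size < 5:
        raise ValueError("need at least 5 positions")
    x = sm.add_constant(np.column_stack([xm, xa]))
    res = sm.OLS(y, x).fit()
    return {
        "params": {"intercept": res.params[0], "myelin": res.params[1],
                   "astro": res.params[2]},
        "bse": {"intercept": res.bse[0], "myelin": res.bse[1], "astro": res.bse[2]},
        "conf_int": res.conf_int(),
        "r_squared": float(res.rsquared),
        "condition_number": float(res.condition_number),
        "collinear": bool(res.condition_number > 1e8),
    }
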