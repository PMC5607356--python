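"""Polarized light imaging: sinusoid fit and neighbourhood FODs.

With circularly polarized light and a rotating analyser at angle rho, the
transmitted intensity through a birefringent myelin sheath follows

    I(rho) = (I0 / 2) * (1 + |sin delta| * sin(2 rho - 2 phi))

where I0 is the transmittance, |sin delta| the retardation (in [0, 1]) and
phi the in-plane fibre orientation (axial, degrees). With equiangular
analyser positions the fit is an exact discrete Fourier solution: I0 from
the mean, retardation and phi from the second harmonic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fod import AxialFOD2D, wrap_axial_deg

__all__ = ["PLIStack", "PLIMaps", "correct_background", "fit_sinusoid", "pli_fod"]

#: Below this retardation the phase (orientation) is numerically meaningless.
RETARDATION_THRESHOLD = 0.05


@dataclass
class PLIStack:
    """Pixel grid of light intensities at each analyser rotation.

    ``intensities``: (H, W, n_angles) non-negative; ``angles_deg``: strictly
    increasing analyser angles in [0, 180), default 0,10,...,170.
    """

    intensities: np.ndarray
    angles_deg: np.ndarray = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (H, W, n_angles)")
        n = self.intensities.shape[-1]
        if self.angles_deg is None:
            self.angles_deg = np.arange(n) * (180.0 / n)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.size != n:
            raise ValueError("one angle per page required")
        if n < 6:
            raise ValueError("need >= 6 analyser angles for a stable fit")
        if np.any(np.diff(self.angles_deg) <= 0) or self.angles_deg[0] < 0 or \
                self.angles_deg[-1] >= 180.0:
            raise ValueError("angles must be strictly increasing in [0, 180)")

    @property
    def is_equiangular(self) -> bool:
        d = np.diff(self.angles_deg)
        return np.allclose(d, d[0]) and np.isclose(
            self.angles_deg[0] + 180.0 - self.angles_deg[-1], d[0]
        )


@dataclass
class PLIMaps:
    """Per-pixel transmittance, axial direction, retardation and validity."""

    transmittance: np.ndarray
    direction: np.ndarray
    retardation: np.ndarray
    valid: np.ndarray


def correct_background(stack: PLIStack, blank: PLIStack | None = None,
                       smooth_sigma: float = 50.0) -> PLIStack:
    """Flat-field correction of a PLI stack.

    With a tissue-free ``blank`` stack: per-pixel, per-angle division by the
    blank intensity (pixels where the blank is zero come back as NaN). A
    stack divided by itself is 1 everywhere. Without a blank, each angle
    image is divided by a unit-mean large-sigma Gaussian estimate of the
    illumination field, which removes smooth vignetting while keeping the
    intensity scale.
    """
    img = stack.intensities
    if blank is not None:
        if blank.intensities.shape != img.shape:
            raise ValueError("blank stack dimensions must match")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = img / blank.intensities
        out[~np.isfinite(out)] = np.nan
        return PLIStack(out, stack.angles_deg.copy())

    from scipy.ndimage import gaussian_filter

    out = np.empty_like(img)
    for a in range(img.shape[-1]):
        illum = gaussian_filter(img[..., a], smooth_sigma, mode="nearest")
        illum = illum / illum.mean()
        out[..., a] = img[..., a] / np.maximum(illum, 1e-12)
    return PLIStack(out, stack.angles_deg.copy())


def fit_sinusoid(stack: PLIStack,
                 retardation_threshold: float = RETARDATION_THRESHOLD) -> PLIMaps:
    """Recover transmittance, retardation and in-plane orientation per pixel.

    Requires equiangular analyser angles (the second-harmonic Fourier
    coefficients are then exact). NaN pixels (e.g. masked by background
    correction) propagate to invalid.
    """
    if not stack.is_equiangular:
        raise ValueError("sinusoid fit requires equiangular analyser angles")
    img = stack.intensities
    if np.any(img[np.isfinite(img)] < 0):
        raise ValueError("negative intensities")
    n = img.shape[-1]
    rho = np.deg2rad(stack.angles_deg)

    mean = img.mean(axis=-1)
    a2 = (2.0 / n) * np.tensordot(img, np.cos(2 * rho), axes=([-1], [0]))
    b2 = (2.0 / n) * np.tensordot(img, np.sin(2 * rho), axes=([-1], [0]))
    # I = (I0/2)(1 + R sin(2rho - 2phi)):
    #   b2 = (I0/2) R cos(2phi),  a2 = -(I0/2) R sin(2phi)
    transmittance = 2.0 * mean
    with np.errstate(divide="ignore", invalid="ignore"):
        retardation = 2.0 * np.hypot(a2, b2) / transmittance
    retardation = np.clip(retardation, 0.0, 1.0)
    direction = wrap_axial_deg(np.rad2deg(0.5 * np.arctan2(-a2, b2)))

    finite = np.isfinite(transmittance) & np.isfinite(retardation)
    retardation = np.where(finite, retardation, 0.0)
    valid = finite & (retardation >= retardation_threshold)
    direction = np.where(valid, direction, np.nan)
    return PLIMaps(transmittance=transmittance, direction=direction,
                   retardation=retardation, valid=valid)


def pli_fod(direction_maps, valid_masks=None, window_px: int = 100,
            n_bins: int = 180, min_valid_frac: float = 0.01):
    """Neighbourhood FODs from one or more slices of direction maps.

    ``direction_maps``: (n_slices, H, W) or (H, W) axial angles in degrees,
    NaN where invalid. Non-overlapping windows of ``window_px`` (anchored at
    the origin, partial edge windows dropped) pool orientations across all
    slices into one normalized histogram per window.

    Returns a (rows, cols) object array of :class:`AxialFOD2D` (None where
    fewer than ``min_valid_frac`` of the window's pixels are valid).
    """
    maps = np.asarray(direction_maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    n_slices, h, w = maps.shape
    if valid_masks is None:
        valid = np.isfinite(maps)
    else:
        valid = np.asarray(valid_masks, dtype=bool)
        if valid.ndim == 2:
            valid = valid[None]
        valid = valid & np.isfinite(maps)

    rows, cols = h // window_px, w // window_px
    out = np.empty((rows, cols), dtype=object)
    for r in range(rows):
        for c in range(cols):
            sl = (slice(None), slice(r * window_px, (r + 1) * window_px),
                  slice(c * window_px, (c + 1) * window_px))
            v = valid[sl]
            if v.sum() < min_valid_frac * v.size:
                out[r, c] = None
                continue
            out[r, c] = AxialFOD2D.from_samples(maps[sl][v], n_bins=n_bins)
    return out
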