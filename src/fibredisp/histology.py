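"""Stain pre-processing and structure-tensor orientation analysis.

Myelin (PLP, DAB-brown) sections use the inverted red channel as the stain
signal; astrocyte (GFAP) sections use the HSV saturation channel.
Haematoxylin-blue cell nuclei are masked by an RGB box threshold and
excluded from all downstream analysis.

Per-pixel fibre orientations come from the structure tensor: the smoothed
outer product of Gaussian-derivative gradients. Texture runs perpendicular
to the dominant gradient, so the orientation is the eigenvector of the
smaller eigenvalue; coherence (lambda1 - lambda2)/(lambda1 + lambda2)
measures local anisotropy. FODs per MRI-voxel-sized patch are histograms of
orientation over suprathreshold, non-nucleus pixels, and the suprathreshold
pixel percentage is the stain's area fraction.

Angle convention: degrees counter-clockwise from the image +x (column)
axis with y pointing up (i.e. a line going "up and to the right" in the
displayed image has a positive angle below 90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .fod import AxialFOD2D, wrap_axial_deg

__all__ = [
    "StainImage",
    "OrientationField",
    "preprocess_stain",
    "structure_tensor_field",
    "histology_fod",
    "NUCLEI_RGB_BOX",
]

#: RGB box (max R, max G, min B) flagging haematoxylin-blue nuclei.
NUCLEI_RGB_BOX = (0.55, 0.55, 0.45)

STAINS = ("plp_myelin", "gfap_astrocyte")


@dataclass
class StainImage:
    """RGB stained-section image with its stain tag and pixel size (um/px)."""

    rgb: np.ndarray
    stain: str
    pixel_size_um: float = 0.28

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValueError("rgb values must lie in [0, 1]")
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain tag {self.stain!r}; expected one of {STAINS}")


@dataclass
class OrientationField:
    """Per-pixel axial orientation, coherence, stain intensity, nuclei mask."""

    theta: np.ndarray
    coherence: np.ndarray
    intensity: np.ndarray
    nuclei_mask: np.ndarray


def preprocess_stain(img: StainImage, nuclei_rgb_box=NUCLEI_RGB_BOX,
                     nuclei_dilate_px: int = 2):
    """Stain intensity image + nuclei mask.

    PLP: inverted red channel (DAB-dark myelin = high signal). GFAP: HSV
    saturation. Nuclei: pixels inside the blue-dominant RGB box, dilated by
    a small margin to cover the partial-volume halo around each nucleus.
    """
    r, g, b = img.rgb[..., 0], img.rgb[..., 1], img.rgb[..., 2]
    r_max, g_max, b_min = nuclei_rgb_box
    nuclei = (r < r_max) & (g < g_max) & (b > b_min)
    if nuclei_dilate_px > 0 and nuclei.any():
        from scipy.ndimage import binary_dilation

        nuclei = binary_dilation(nuclei, iterations=nuclei_dilate_px)
    if img.stain == "plp_myelin":
        intensity = 1.0 - r
    else:
        intensity = rgb2hsv(img.rgb)[..., 1]
    return intensity, nuclei


def structure_tensor_field(intensity, sigma_grad: float = 2.0,
                           sigma_window: float = 10.0,
                           nuclei_mask=None) -> OrientationField:
    """Structure-tensor orientation and coherence per pixel.

    Gradients are Gaussian derivatives at ``sigma_grad``; the tensor is
    window-averaged with a Gaussian of ``sigma_window`` (must be larger).
    A constant image returns coherence 0 and masked (NaN) orientations.
    """
    if sigma_grad >= sigma_window:
        raise ValueError("sigma_grad must be smaller than sigma_window")
    img = np.asarray(intensity, dtype=float)
    # y points up in the angle convention while rows grow downward
    gx = gaussian_filter(img, sigma_grad, order=(0, 1), mode="nearest")
    gy = -gaussian_filter(img, sigma_grad, order=(1, 0), mode="nearest")
    jxx = gaussian_filter(gx * gx, sigma_window, mode="nearest")
    jyy = gaussian_filter(gy * gy, sigma_window, mode="nearest")
    jxy = gaussian_filter(gx * gy, sigma_window, mode="nearest")

    trace = jxx + jyy
    # dominant gradient direction; texture orientation is perpendicular
    theta_grad = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
    theta = wrap_axial_deg(np.rad2deg(theta_grad) + 90.0)
    diff = np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        coherence = np.where(trace > 0, diff / np.maximum(trace, 1e-300), 0.0)
    theta = np.where(trace > 1e-300, theta, np.nan)

    if nuclei_mask is None:
        nuclei_mask = np.zeros(img.shape, dtype=bool)
    return OrientationField(theta=theta, coherence=coherence,
                            intensity=img, nuclei_mask=np.asarray(nuclei_mask, bool))


def histology_fod(field: OrientationField, patch_px: int = 1400,
                  intensity_threshold: float | None = None,
                  n_bins: int = 180):
    """Per-patch FOD and area fraction.

    Non-overlapping ``patch_px`` patches anchored at the image origin
    (partial edge patches dropped). Within each patch, orientations of
    pixels with stain intensity >= threshold (Otsu on the patch when not
    given) and outside the nuclei mask are histogrammed; the area fraction
    is the suprathreshold share of non-nucleus pixels.

    Returns ``(fods, area_fractions)``: a (rows, cols) object array of
    :class:`AxialFOD2D` (None where no pixel qualifies) and a matching
    float array.
    """
    h, w = field.intensity.shape
    rows, cols = h // patch_px, w // patch_px
    fods = np.empty((rows, cols), dtype=object)
    areas = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            sl = (slice(r * patch_px, (r + 1) * patch_px),
                  slice(c * patch_px, (c + 1) * patch_px))
            inten = field.intensity[sl]
            nuc = field.nuclei_mask[sl]
            theta = field.theta[sl]
            tissue = ~nuc
            if tissue.sum() == 0:
                fods[r, c] = None
                continue
            if intensity_threshold is None:
                vals = inten[tissue]
                try:
                    thr = threshold_otsu(vals) if np.ptp(vals) > 1e-12 else np.inf
                except ValueError:
                    thr = np.inf
            else:
                thr = intensity_threshold
            fg = tissue & (inten >= thr)
            areas[r, c] = fg.sum() / tissue.sum()
            use = fg & np.isfinite(theta)
            if use.sum() == 0:
                fods[r, c] = None
                continue
            fods[r, c] = AxialFOD2D.from_samples(theta[use], n_bins=n_bins)
    return fods, areas
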