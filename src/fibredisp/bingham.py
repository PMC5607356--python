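"""Bingham axial-distribution machinery shared by all modalities.

The fibre orientation distribution of a dispersed fibre population is
modelled with the Bingham distribution, the antipodally symmetric analogue
of a Gaussian on the sphere:

    p(n) = exp(-k1 (mu1.n)^2 - k2 (mu2.n)^2) / Z(k1, k2)

with orthonormal axes (mu0, mu1, mu2) and concentrations k1 >= k2 >= 0.
Probability mass concentrates around the principal axis mu0; a *large* k
along an axis means *little* spread toward that axis, so low k corresponds
to high dispersion. k1 = k2 = kappa reduces to the Watson distribution.

Restricted to a great circle, the Bingham becomes the one-parameter
in-plane law

    p(theta) = exp(-k2d sin^2(theta - mu)) / (pi exp(-k2d/2) I0(k2d/2))

which in the double angle 2*theta is exactly a von Mises distribution with
concentration k2d/2. The scalar orientation dispersion index

    ODI = (2/pi) * arctan(1 / k)

maps concentration to [0, 1]: 0 = perfectly parallel fibres, 1 = uniform
on the circle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, special

from .fod import AxialFOD2D, wrap_axial_deg
from .quadrature import sphere_grid

__all__ = [
    "Bingham3",
    "Bingham2",
    "odi_from_k",
    "k_from_odi",
    "bingham3_density",
    "restrict_to_plane",
    "fit_bingham2",
    "sample_bingham3",
    "K_MAX",
]

#: Concentration cap. ODI(128) ~ 0.005, below the angular resolution of the
#: microscopy binning, so larger values are indistinguishable from "parallel".
K_MAX = 128.0

_ORTHO_TOL = 1e-8


class DegenerateOrientationError(ValueError):
    """Principal axis (anti)parallel to the requested projection plane normal."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bingham3:
    """3D Bingham parameters.

    ``axes`` columns are (mu0, mu1, mu2): principal axis then the two
    dispersion axes, concentrations ``k1 >= k2 >= 0`` along mu1 and mu2.
    """

    axes: np.ndarray
    k1: float
    k2: float

    def __post_init__(self):
        axes = np.asarray(self.axes, dtype=float)
        if axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix")
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-6):
            raise ValueError("axes must be orthonormal")
        # re-orthonormalize to tight tolerance so downstream quadrature is exact
        u, _, vt = np.linalg.svd(axes)
        axes = u @ vt
        assert np.allclose(axes.T @ axes, np.eye(3), atol=_ORTHO_TOL)
        object.__setattr__(self, "axes", axes)
        if not (self.k1 >= self.k2 >= 0):
            raise ValueError("need k1 >= k2 >= 0")

    @property
    def mu0(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def mu1(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def mu2(self) -> np.ndarray:
        return self.axes[:, 2]

    @classmethod
    def from_principal_axis(cls, mu0, k1: float, k2: float, roll_deg: float = 0.0):
        """Build axes from a principal direction; mu1/mu2 fixed by ``roll_deg``."""
        mu0 = np.asarray(mu0, dtype=float)
        mu0 = mu0 / np.linalg.norm(mu0)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(mu0 @ helper) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        a = np.cross(mu0, helper)
        a /= np.linalg.norm(a)
        b = np.cross(mu0, a)
        r = np.deg2rad(roll_deg)
        mu1 = np.cos(r) * a + np.sin(r) * b
        mu2 = -np.sin(r) * a + np.cos(r) * b
        return cls(np.column_stack([mu0, mu1, mu2]), k1, k2)


@dataclass(frozen=True)
class Bingham2:
    """In-plane Bingham: axial mean ``mu`` (degrees in [0,180)) and k2d >= 0."""

    mu: float
    k2d: float

    def __post_init__(self):
        if not np.isfinite(self.k2d) or self.k2d < 0:
            raise ValueError("k2d must be finite and >= 0")
        object.__setattr__(self, "mu", float(wrap_axial_deg(self.mu)))

    @property
    def odi(self) -> float:
        return odi_from_k(self.k2d)

    def density(self, theta_deg) -> np.ndarray:
        """Density per radian on the axial half-circle [0, pi)."""
        return np.exp(self.log_density(theta_deg))

    def log_density(self, theta_deg) -> np.ndarray:
        # normalization pi * exp(-k/2) * I0(k/2) == pi * i0e(k/2): the scaled
        # Bessel absorbs the exp(-k/2) factor, stable up to the k cap
        d = np.deg2rad(np.asarray(theta_deg, dtype=float) - self.mu)
        return -self.k2d * np.sin(d) ** 2 - np.log(np.pi * special.i0e(self.k2d / 2.0))

    def sample(self, n: int, rng) -> np.ndarray:
        """Draw axial angles (degrees) via the double-angle von Mises."""
        two_theta = rng.vonmises(np.deg2rad(2.0 * self.mu), self.k2d / 2.0, size=n)
        return wrap_axial_deg(np.rad2deg(two_theta) / 2.0)

    def to_json(self, path):
        Path(path).write_text(
            json.dumps({"mu_deg": self.mu, "k2d": self.k2d, "odi": self.odi})
        )


# ---------------------------------------------------------------------------
# scalar dispersion index
# ---------------------------------------------------------------------------


def odi_from_k(k):
    """Orientation dispersion index ODI = (2/pi) arctan(1/k), in [0, 1]."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("concentration k must be >= 0")
    with np.errstate(divide="ignore"):
        out = (2.0 / np.pi) * np.arctan2(1.0, k)
    return out if out.ndim else float(out)


def k_from_odi(odi):
    """Inverse of :func:`odi_from_k` (odi in (0, 1])."""
    odi = np.asarray(odi, dtype=float)
    if np.any((odi <= 0) | (odi > 1)):
        raise ValueError("odi must lie in (0, 1]")
    out = 1.0 / np.tan(np.pi * odi / 2.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# 3D density, normalization, restriction
# ---------------------------------------------------------------------------


def _log_kernel(params: Bingham3, directions: np.ndarray) -> np.ndarray:
    c1 = directions @ params.mu1
    c2 = directions @ params.mu2
    return -(params.k1 * c1**2 + params.k2 * c2**2)


def bingham_lognorm(params: Bingham3, n_polar: int = 64, n_azimuth: int = 128) -> float:
    """log of the normalization constant Z = integral of the kernel over S2."""
    pts, wts = sphere_grid(n_polar, n_azimuth)
    lk = _log_kernel(params, pts)
    m = lk.max()
    return float(m + np.log(np.sum(wts * np.exp(lk - m))))


def bingham3_density(params: Bingham3, directions, n_polar: int = 64, n_azimuth: int = 128):
    """Bingham density at unit ``directions`` (shape (..., 3)).

    Normalized by spherical quadrature; antipodally symmetric by
    construction. Raises if directions are not unit norm.
    """
    directions = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(directions, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("directions must be unit vectors")
    lz = bingham_lognorm(params, n_polar, n_azimuth)
    return np.exp(_log_kernel(params, directions) - lz)


def sample_bingham3(params: Bingham3, n: int, rng) -> np.ndarray:
    """Rejection-sample unit vectors from a 3D Bingham distribution.

    The kernel is bounded by 1 (attained on the principal axis), so uniform
    sphere proposals accepted with probability exp(log-kernel) are exact.
    """
    out = np.empty((0, 3))
    # acceptance rate ~ Z / 4pi; draw in chunks sized accordingly
    z = np.exp(bingham_lognorm(params))
    rate = max(z / (4 * np.pi), 1e-3)
    while out.shape[0] < n:
        m = int((n - out.shape[0]) / rate * 1.2) + 64
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        keep = rng.random(m) < np.exp(_log_kernel(params, v))
        out = np.vstack([out, v[keep]])
    return out[:n]


def restrict_to_plane(params: Bingham3, plane_normal) -> Bingham2:
    """Restrict a 3D Bingham to the great circle in the given plane.

    The exponent is the quadratic form -n^T Q n with
    Q = k1 mu1 mu1^T + k2 mu2 mu2^T. On the great circle with the given
    normal, the restricted 2x2 form has eigenvalues a_low <= a_high; the
    in-plane law is a Bingham2 with concentration ``k2d = a_high - a_low``
    (contrast along vs across the in-plane principal axis) and mean axis
    along the low-eigenvalue eigenvector (the in-plane projection of mu0).
    """
    v = np.asarray(plane_normal, dtype=float)
    v = v / np.linalg.norm(v)
    cos_to_normal = abs(params.mu0 @ v)
    if cos_to_normal > 1.0 - 1e-6:
        raise DegenerateOrientationError(
            "principal axis is parallel to the plane normal; in-plane "
            "orientation is undefined"
        )
    if cos_to_normal > np.cos(np.deg2rad(10.0)) and (params.k1 > 0 or params.k2 > 0):
        warnings.warn(
            "principal axis within 10 degrees of the plane normal; "
            "in-plane restriction is poorly conditioned",
            RuntimeWarning,
            stacklevel=2,
        )
    # orthonormal in-plane frame (e1, e2); for the canonical z-normal plane
    # this is exactly (x, y) so angles follow the image convention
    helper = np.array([0.0, 1.0, 0.0]) if abs(v[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(helper, v)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    q = params.k1 * np.outer(params.mu1, params.mu1) + params.k2 * np.outer(
        params.mu2, params.mu2
    )
    basis = np.column_stack([e1, e2])
    q2 = basis.T @ q @ basis
    evals, evecs = np.linalg.eigh(q2)
    k2d = float(min(evals[1] - evals[0], K_MAX))
    low = evecs[:, 0]
    if k2d <= 1e-12:
        # isotropic in-plane; align the (arbitrary) mean with mu0's projection
        proj = basis.T @ params.mu0
        low = proj if np.linalg.norm(proj) > 1e-12 else np.array([1.0, 0.0])
    vec3 = basis @ low
    mu = _inplane_angle_deg(vec3, v, e1, e2)
    return Bingham2(mu=mu, k2d=k2d)


def _inplane_angle_deg(vec3, normal, e1, e2) -> float:
    """Axial angle of an in-plane 3-vector in the (e1, e2) frame.

    For the canonical z-normal plane the frame is (x, y) so the angle is the
    usual counter-clockwise-from-+x image convention.
    """
    x = vec3 @ e1
    y = vec3 @ e2
    return float(wrap_axial_deg(np.rad2deg(np.arctan2(y, x))))


# ---------------------------------------------------------------------------
# ML fit of the in-plane Bingham to a binned FOD
# ---------------------------------------------------------------------------


def fit_bingham2(fod: AxialFOD2D, k_max: float = K_MAX) -> Bingham2:
    """Maximum-likelihood Bingham2 fit to a binned axial FOD.

    The mean axis comes in closed form from the double-angle trigonometric
    moment; the concentration maximizes the binned log-likelihood by bounded
    scalar optimization over [0, k_max]. A delta FOD saturates at ``k_max``.
    """
    total = fod.mass.sum()
    if total <= 0:
        raise ValueError("empty FOD: all-zero mass")
    mass = fod.mass / total
    t2 = np.deg2rad(2.0 * fod.bin_centers)
    c = float(np.sum(mass * np.cos(t2)))
    s = float(np.sum(mass * np.sin(t2)))
    rbar = np.hypot(c, s)
    mu = wrap_axial_deg(np.rad2deg(0.5 * np.arctan2(s, c)))

    sin2 = np.sin(np.deg2rad(fod.bin_centers - mu)) ** 2
    w_sin2 = float(np.sum(mass * sin2))

    def neg_loglik(k):
        # -sum_i m_i log p(theta_i) = k <sin^2> + log(pi i0e(k/2))
        return k * w_sin2 + np.log(np.pi * special.i0e(k / 2.0))
    res = optimize.minimize_scalar(
        neg_loglik, bounds=(0.0, k_max), method="bounded", options={"xatol": 1e-6}
    )
    k = float(res.x)
    # the bounded optimizer never returns the exact endpoints; snap to them
    if neg_loglik(0.0) <= res.fun:
        k = 0.0
    elif neg_loglik(k_max) <= res.fun:
        k = k_max
    if rbar < 1e-12:
        k = 0.0
    return Bingham2(mu=mu, k2d=k)
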