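"""Area-fraction to volume-fraction mapping and FOD combination.

A thin physical section reports an *area* fraction of stained structure,
but the quantity entering the myelin/astrocyte FOD combination is a
*volume* fraction. For an infinitesimally thin section the two coincide
(Delesse's stereological principle), but a section of finite thickness
projects structure from its whole depth, inflating the apparent area
fraction. The mapping is built by simulation: straight, randomly oriented
overlapping cylinders are packed into a voxel box at increasing volume
fractions, a central slab of the section thickness is max-projected, and
the foreground fraction of the projection is recorded.

The combined myelin+astrocyte FOD is the convex combination

    FOD_MA(theta) = f_M * FOD_M(theta) + f_A * FOD_A(theta)

with the volume fractions rescaled so that f_M + f_A = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fod import AxialFOD2D

__all__ = [
    "AreaVolumeMap",
    "CompartmentFractions",
    "simulate_area_volume_map",
    "area_to_volume",
    "combine_fods",
    "scale_fractions",
]


@dataclass
class AreaVolumeMap:
    """Monotone simulated mapping volume fraction -> mean area fraction."""

    volume_fractions: np.ndarray
    area_fractions: np.ndarray
    slab_thickness_px: int
    fibre_radius_px: float
    n_reps: int
    seed: int

    def __post_init__(self):
        v = np.asarray(self.volume_fractions, dtype=float)
        a = np.asarray(self.area_fractions, dtype=float)
        if v.shape != a.shape or v.ndim != 1:
            raise ValueError("volume and area grids must be matching 1-D arrays")
        if np.any(np.diff(v) <= 0):
            raise ValueError("volume grid must be strictly increasing")
        if np.any(np.diff(a) < 0):
            raise ValueError("area fractions must be non-decreasing")
        if not (v[0] == 0.0 and a[0] == 0.0):
            raise ValueError("map must pass through (0, 0)")
        self.volume_fractions, self.area_fractions = v, a

    def to_csv(self, path, sidecar_json=None):
        pd.DataFrame({"volume_fraction": self.volume_fractions,
                      "area_fraction": self.area_fractions}).to_csv(path, index=False)
        if sidecar_json is not None:
            Path(sidecar_json).write_text(json.dumps({
                "slab_thickness_px": self.slab_thickness_px,
                "fibre_radius_px": self.fibre_radius_px,
                "n_reps": self.n_reps, "seed": self.seed,
            }))

    @classmethod
    def from_csv(cls, path, slab_thickness_px=0, fibre_radius_px=0.0,
                 n_reps=0, seed=0):
        df = pd.read_csv(path)
        return cls(df["volume_fraction"].to_numpy(), df["area_fraction"].to_numpy(),
                   slab_thickness_px, fibre_radius_px, n_reps, seed)


@dataclass(frozen=True)
class CompartmentFractions:
    """Myelin and astrocyte volume fractions, scaled to sum to one."""

    f_m: float
    f_a: float

    def __post_init__(self):
        if self.f_m < 0 or self.f_a < 0:
            raise ValueError("fractions must be >= 0")
        if abs(self.f_m + self.f_a - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 (use scale_fractions)")


def _rasterize_cylinder(coords, point, direction, radius, box):
    """Boolean mask of voxels within ``radius`` of an infinite line.

    Displacements use the minimal image convention (periodic box), which
    makes the Boolean cylinder model stationary: without wrapping, coverage
    drops towards the box faces and a central virtual slice would be biased
    relative to the whole-box volume fraction.
    """
    w = np.mod(coords - point + box / 2.0, box) - box / 2.0  # (N, 3)
    proj = w @ direction
    d2 = np.einsum("ij,ij->i", w, w) - proj**2
    return d2 <= radius**2


def simulate_area_volume_map(volume_grid=None, fibre_radius_px: float = 2.0,
                             slab_thickness_px: int = 21, box_px: int = 64,
                             n_reps: int = 3, seed: int = 0) -> AreaVolumeMap:
    """Monte-Carlo mapping from fibre volume fraction to section area fraction.

    Straight cylinders with uniformly random orientation (uniform on the
    hemisphere) and position are unioned into a ``box_px``^3 boolean volume
    until each target volume fraction on the grid is reached; a central slab
    of ``slab_thickness_px`` is max-projected along its thickness and the
    projected foreground fraction recorded. The result, averaged over
    ``n_reps`` repetitions, is made monotone by isotonic adjustment so it is
    invertible despite Monte-Carlo noise.

    The default slab thickness (21 px) is the histology section thickness
    over the pixel size, 6 um / 0.28 um.
    """
    if volume_grid is None:
        volume_grid = np.linspace(0.0, 0.6, 13)
    volume_grid = np.asarray(volume_grid, dtype=float)
    if volume_grid[0] != 0.0:
        volume_grid = np.concatenate([[0.0], volume_grid])
    if fibre_radius_px < 1.0:
        raise ValueError("fibre radius must be >= 1 px")
    if slab_thickness_px < 1:
        raise ValueError("slab thickness must be >= 1 px")
    if box_px < 20 * fibre_radius_px:
        raise ValueError("box must be at least 20x the fibre radius")
    # overlapping cylinders cannot fill space beyond ~1 - exp(-lambda); with a
    # finite box the practical ceiling is below 0.95
    if volume_grid[-1] > 0.95:
        raise ValueError("target volume fraction beyond the packing limit; "
                         "maximum supported is 0.95")

    rng = np.random.default_rng(seed)
    ax = np.arange(box_px, dtype=float)
    coords = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    z0 = box_px // 2 - slab_thickness_px // 2
    z0 = max(z0, 0)
    z1 = min(z0 + slab_thickness_px, box_px)

    areas = np.zeros((n_reps, volume_grid.size))
    for rep in range(n_reps):
        vol = np.zeros(box_px**3, dtype=bool)
        achieved = 0.0
        next_i = 1  # grid[0] == 0 -> area 0 by construction
        while next_i < volume_grid.size:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            p = rng.uniform(0, box_px, size=3)
            vol |= _rasterize_cylinder(coords, p, u, fibre_radius_px, box_px)
            achieved = vol.mean()
            while next_i < volume_grid.size and achieved >= volume_grid[next_i]:
                v3 = vol.reshape(box_px, box_px, box_px)
                proj = v3[:, :, z0:z1].any(axis=2)
                areas[rep, next_i] = proj.mean()
                next_i += 1

    mean_area = areas.mean(axis=0)
    # isotonic L2 projection: guarantees invertibility without the upward
    # drift a running maximum would accumulate from Monte-Carlo jitter
    from scipy.optimize import isotonic_regression

    mean_area = isotonic_regression(mean_area).x
    mean_area[0] = 0.0
    return AreaVolumeMap(volume_grid, mean_area, slab_thickness_px,
                         fibre_radius_px, n_reps, seed)


def area_to_volume(area_fraction, map: AreaVolumeMap):
    """Invert the map by monotone linear interpolation (clamped with warning)."""
    import warnings

    a = np.asarray(area_fraction, dtype=float)
    amax = map.area_fractions[-1]
    if np.any(a > amax + 1e-12):
        warnings.warn("area fraction above the simulated range; clamping",
                      RuntimeWarning, stacklevel=2)
    a = np.clip(a, 0.0, amax)
    # np.interp needs strictly increasing x; collapse flat runs
    av, vv = map.area_fractions, map.volume_fractions
    keep = np.concatenate([[True], np.diff(av) > 0])
    out = np.interp(a, av[keep], vv[keep])
    return out if out.ndim else float(out)


def scale_fractions(f_m_raw: float, f_a_raw: float) -> CompartmentFractions:
    """Proportionally rescale raw volume fractions so f_M + f_A = 1."""
    if f_m_raw < 0 or f_a_raw < 0:
        raise ValueError("fractions must be >= 0")
    total = f_m_raw + f_a_raw
    if total <= 0:
        raise ValueError("cannot scale: both fractions are zero")
    f_m = f_m_raw / total
    # complement rather than f_a_raw/total so the sum is exactly 1 in floats
    return CompartmentFractions(f_m=f_m, f_a=1.0 - f_m)


def combine_fods(fod_m: AxialFOD2D, fod_a: AxialFOD2D,
                 fractions: CompartmentFractions) -> AxialFOD2D:
    """FOD_MA = f_M FOD_M + f_A FOD_A (bin-wise convex combination)."""
    if fod_m.n_bins != fod_a.n_bins or not np.allclose(fod_m.bin_edges, fod_a.bin_edges):
        raise ValueError("FODs must share the same bin grid")
    mass = fractions.f_m * fod_m.mass + fractions.f_a * fod_a.mass
    return AxialFOD2D(fod_m.bin_edges, mass)
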