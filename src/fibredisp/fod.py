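"""In-plane axial fibre orientation distributions (FODs).

An :class:`AxialFOD2D` is the common currency of every modality in this
package: a normalized histogram of axial (mod-180°) in-plane fibre
orientations. Angles are in degrees, measured counter-clockwise from the
image +x axis, with half-open bins ``[a, b)`` over ``[0°, 180°)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AxialFOD2D"]


def wrap_axial_deg(theta):
    """Wrap angles (degrees) into the axial range [0, 180)."""
    return np.mod(theta, 180.0)


@dataclass
class AxialFOD2D:
    """Normalized histogram over in-plane axial orientations [0°, 180°).

    Parameters
    ----------
    bin_edges : (n+1,) increasing edges spanning [0, 180].
    mass : (n,) non-negative weights; normalized to sum to one.
    """

    bin_edges: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.bin_edges.ndim != 1 or self.mass.ndim != 1:
            raise ValueError("bin_edges and mass must be 1-D")
        if self.bin_edges.size != self.mass.size + 1:
            raise ValueError("need len(bin_edges) == len(mass) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not (abs(self.bin_edges[0]) < 1e-9 and abs(self.bin_edges[-1] - 180.0) < 1e-9):
            raise ValueError("bin_edges must span [0, 180]")
        if np.any(self.mass < 0):
            raise ValueError("mass must be non-negative")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_samples(cls, angles_deg, n_bins: int = 180, weights=None) -> "AxialFOD2D":
        """Histogram axial angle samples (degrees, any range) into an FOD."""
        angles = wrap_axial_deg(np.asarray(angles_deg, dtype=float).ravel())
        edges = np.linspace(0.0, 180.0, n_bins + 1)
        mass, _ = np.histogram(angles, bins=edges, weights=weights)
        total = mass.sum()
        if total <= 0:
            raise ValueError("empty FOD: no samples")
        return cls(edges, mass / total)

    @classmethod
    def uniform(cls, n_bins: int = 180) -> "AxialFOD2D":
        edges = np.linspace(0.0, 180.0, n_bins + 1)
        return cls(edges, np.full(n_bins, 1.0 / n_bins))

    @classmethod
    def delta(cls, angle_deg: float, n_bins: int = 180) -> "AxialFOD2D":
        edges = np.linspace(0.0, 180.0, n_bins + 1)
        mass = np.zeros(n_bins)
        idx = int(np.floor(wrap_axial_deg(angle_deg) / 180.0 * n_bins)) % n_bins
        mass[idx] = 1.0
        return cls(edges, mass)

    # -- views -------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.mass.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def normalized(self) -> "AxialFOD2D":
        total = self.mass.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero FOD")
        return AxialFOD2D(self.bin_edges, self.mass / total)

    def circular_mean_deg(self) -> float:
        """Axial mean direction via the double-angle representation."""
        t2 = np.deg2rad(2.0 * self.bin_centers)
        c = float(np.sum(self.mass * np.cos(t2)))
        s = float(np.sum(self.mass * np.sin(t2)))
        return wrap_axial_deg(np.rad2deg(0.5 * np.arctan2(s, c)))

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path):
        """Write ``angle_deg,mass`` rows (one per bin centre)."""
        pd.DataFrame({"angle_deg": self.bin_centers, "mass": self.mass}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "AxialFOD2D":
        df = pd.read_csv(path)
        centers = df["angle_deg"].to_numpy(dtype=float)
        width = np.diff(centers)
        if centers.size < 2 or not np.allclose(width, width[0]):
            raise ValueError("FOD CSV must hold equispaced bin centres")
        edges = np.concatenate([centers - width[0] / 2, [centers[-1] + width[0] / 2]])
        # tolerate round-off on the outer edges
        edges[0] = max(edges[0], 0.0)
        edges[-1] = min(edges[-1], 180.0)
        return cls(edges, df["mass"].to_numpy(dtype=float)).normalized()

    def to_json(self, path):
        Path(path).write_text(
            json.dumps({"bin_edges": self.bin_edges.tolist(), "mass": self.mass.tolist()})
        )

    @classmethod
    def from_json(cls, path) -> "AxialFOD2D":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["bin_edges"]), np.asarray(d["mass"]))
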