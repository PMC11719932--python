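"""Core containers shared by all analysis stages.

All physical quantities are in nanometres (nm) internally; unit conversion
happens only at I/O boundaries.  The image origin convention is: centre of
the top-left pixel at (0, 0), x increasing rightward (columns), y increasing
downward (rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised when a file does not parse under its declared dialect."""


@dataclass(frozen=True)
class HeightMap:
    """A calibrated AFM topography image.

    Parameters
    ----------
    heights
        2D array of surface heights in nm, shape ``(rows, cols)``.
    pixel_size
        Physical edge length of one pixel in nm/pixel; must be positive.
    """

    heights: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2 or h.size == 0:
            raise ValidationError("heights must be a non-empty 2D grid")
        if not np.all(np.isfinite(h)):
            raise ValidationError("heights must be finite")
        if not (self.pixel_size > 0):
            raise ValidationError("pixel_size must be positive")
        object.__setattr__(self, "heights", h)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (width, height) of the scanned frame in nm."""
        rows, cols = self.heights.shape
        return cols * self.pixel_size, rows * self.pixel_size


@dataclass(frozen=True)
class Particle:
    """A detected surface object.

    ``height`` is the maximum height within the footprint; ``area`` is the
    footprint area in nm².  ``touches_border`` flags objects clipped by the
    frame edge (kept for height statistics, handled by edge corrections in
    the pair-correlation estimator).
    """

    x: float
    y: float
    height: float
    area: float
    touches_border: bool = False

    def __post_init__(self) -> None:
        if not (self.height > 0):
            raise ValidationError("particle height must be positive")
        if not (self.area > 0):
            raise ValidationError("particle area must be positive")


@dataclass(frozen=True)
class PointPattern:
    """Particle centroids inside a rectangular observation window.

    The window is ``[0, width) x [0, height)`` in nm.  Optional per-point
    heights carry the AFM height mark along with each position.
    """

    points: np.ndarray
    window: tuple[float, float]
    heights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ValidationError("window sides must be positive")
        if pts.size and (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() > w
            or pts[:, 1].max() > h
        ):
            raise ValidationError("all points must lie inside the window")
        object.__setattr__(self, "points", pts)
        if self.heights is not None:
            hh = np.asarray(self.heights, dtype=float)
            if hh.shape[0] != pts.shape[0]:
                raise ValidationError("heights must match points one-to-one")
            object.__setattr__(self, "heights", hh)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        return float(self.window[0] * self.window[1])

    @property
    def density(self) -> float:
        """Intensity estimate λ̂ = N / window area (points per nm²)."""
        return self.n / self.area


@dataclass(frozen=True)
class DetectionConfig:
    """Particle-detection parameters.

    The 0.5 nm default threshold is the empirical noise floor of clean mica
    scans: control experiments on bare substrate show no objects taller than
    0.5 nm, so anything above it is treated as an adsorbed particle.
    """

    height_threshold: float = 0.5
    min_area: float = 0.0
    smoothing_scale: float = 0.0
    local_background: bool = False

    def __post_init__(self) -> None:
        if self.height_threshold < 0:
            raise ValidationError("height_threshold must be >= 0")
        if self.min_area < 0:
            raise ValidationError("min_area must be >= 0")
        if self.smoothing_scale < 0:
            raise ValidationError("smoothing_scale must be >= 0")


def as_point_array(points: Sequence) -> np.ndarray:
    """Coerce any (N, 2) point sequence to a float ndarray."""
    return np.asarray(points, dtype=float).reshape(-1, 2)
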