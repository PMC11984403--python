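"""Tumor ROI geometry: concentric ellipse rings, biopsy cylinders, averaging.

Subcutaneous gliomas typically show a rim of high proliferation around a
quieter core, so the tumor slice is partitioned into concentric donut-
shaped elliptical zones (outer ring m=1 ... innermost m=n_rings) derived
from the minimum axis-aligned rectangle enclosing the tumor mask.  Biopsy
specimens are modelled as small cylinders (2 mm diameter x 10 mm height)
rasterized into image space; all downstream pharmacokinetic fitting runs
on the ROI-averaged signal (averaging precedes fitting).

Pixel convention: 0-based indices, coordinates at pixel centers,
x = column and y = row; ellipse membership is inclusive of the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EllipseRingSpec",
    "BiopsyCylinder",
    "min_enclosing_rectangle",
    "concentric_ring_rois",
    "biopsy_mask",
    "roi_average_timecourse",
]


@dataclass(frozen=True)
class EllipseRingSpec:
    """Geometry of the concentric ring partition.

    ``(X_R, Y_R)`` is the center of the minimum enclosing rectangle in
    (x=col, y=row) pixel coordinates; ``L_R``/``W_R`` its length (x extent)
    and width (y extent) in pixels.  Ellipse ``m`` (1-based) has semi-axes
    shrunk by ``q`` per step: geometric law ``a_m = (L_R/2) q^(m-1)``
    (default), or the linear alternative ``a_m = (L_R/2) (1-(1-q)(m-1))``.
    """

    X_R: float
    Y_R: float
    L_R: float
    W_R: float
    q: float = 0.75
    n_rings: int = 6
    shrink: str = "geometric"

    def __post_init__(self) -> None:
        if self.L_R <= 0 or self.W_R <= 0:
            raise ValueError("rectangle extents must be positive")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")
        if self.n_rings < 2:
            raise ValueError("need at least 2 rings")
        if self.shrink not in {"geometric", "linear"}:
            raise ValueError(f"unknown shrink law {self.shrink!r}")

    def semi_axes(self, m: int) -> tuple[float, float]:
        """Semi-axes (a_m, b_m) of ellipse ``m`` (1-based)."""
        if self.shrink == "geometric":
            s = self.q ** (m - 1)
        else:
            s = max(1.0 - (1.0 - self.q) * (m - 1), 1e-9)
        return 0.5 * self.L_R * s, 0.5 * self.W_R * s


@dataclass(frozen=True)
class BiopsyCylinder:
    """Stereotactic biopsy specimen: a cylinder in world (mm) coordinates."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    diameter: float = 2.0
    height: float = 10.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("cylinder diameter and height must be positive")
        if np.linalg.norm(self.axis) == 0:
            raise ValueError("axis direction must be non-zero")

    @property
    def volume_mm3(self) -> float:
        return np.pi * (self.diameter / 2.0) ** 2 * self.height


def min_enclosing_rectangle(mask: np.ndarray) -> EllipseRingSpec:
    """Axis-aligned minimum rectangle enclosing a binary mask.

    Returns an :class:`EllipseRingSpec` with default ring settings
    (q = 0.75, six rings) centred on the box midpoint.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(mask)
    y0, y1 = rows.min(), rows.max()
    x0, x1 = cols.min(), cols.max()
    return EllipseRingSpec(
        X_R=0.5 * (x0 + x1),
        Y_R=0.5 * (y0 + y1),
        L_R=float(x1 - x0 + 1),
        W_R=float(y1 - y0 + 1),
    )


def concentric_ring_rois(mask: np.ndarray, spec: EllipseRingSpec) -> np.ndarray:
    """Partition a tumor mask into concentric elliptical donut ROIs.

    ROI ``m`` (label value m, 1-based) contains the pixels inside ellipse
    ``m`` but outside ellipse ``m+1``; the innermost ROI is the interior of
    the last ellipse.  All ROIs are intersected with the tumor mask, so the
    labels are disjoint and their union equals mask ∩ ellipse 1.
    """
    mask = np.asarray(mask, dtype=bool)
    yy, xx = np.indices(mask.shape)
    labels = np.zeros(mask.shape, dtype=np.uint16)

    def inside(m: int) -> np.ndarray:
        a, b = spec.semi_axes(m)
        return ((xx - spec.X_R) / a) ** 2 + ((yy - spec.Y_R) / b) ** 2 <= 1.0

    inner = inside(1)
    for m in range(1, spec.n_rings + 1):
        outer = inner
        if m < spec.n_rings:
            inner = inside(m + 1)
            ring = outer & ~inner
        else:
            ring = outer
        labels[ring & mask] = m
    return labels


def biopsy_mask(
    cyl: BiopsyCylinder,
    shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float] | float,
) -> np.ndarray:
    """Rasterize a biopsy cylinder: voxels whose centers fall inside it.

    ``voxel_size_mm`` may be isotropic (scalar) or per-axis; world
    coordinates of voxel (i, j, k) are ``(i+0.5, j+0.5, k+0.5) * voxel``.
    """
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (voxel_size_mm,) * 3
    vox = np.asarray(voxel_size_mm, dtype=float)
    axis = np.asarray(cyl.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    center = np.asarray(cyl.center, dtype=float)

    grids = np.meshgrid(*[(np.arange(n) + 0.5) * v for n, v in zip(shape, vox)],
                        indexing="ij")
    coords = np.stack(grids, axis=-1) - center
    axial = coords @ axis
    radial_sq = (coords ** 2).sum(axis=-1) - axial ** 2
    mask = (np.abs(axial) <= cyl.height / 2.0) & (
        radial_sq <= (cyl.diameter / 2.0) ** 2
    )
    if not mask.any():
        raise ValueError("cylinder does not intersect the image grid")
    return mask


def roi_average_timecourse(series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-frame arithmetic mean of a 4D series over a spatial mask.

    ``series`` has time on the last axis; averaging precedes any fitting.
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape[:-1]:
        raise ValueError("mask shape must match the spatial shape of series")
    if not mask.any():
        raise ValueError("empty mask")
    return series[mask].mean(axis=0)
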