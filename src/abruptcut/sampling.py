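"""Peripheral sampling regions along the lesion border.

Three placements:

* method 1 — full circular disks centered on the traced boundary itself
  (regions intentionally include pixels outside the lesion);
* method 2 — disks centered on an inner border obtained by shifting each
  boundary point ``r`` pixels along its own unit vector toward the
  centroid, then intersected with the lesion;
* method 3 — disks centered on an inner border obtained by uniformly
  scaling the boundary about the centroid so the starting point moves
  inward exactly ``r``, then intersected with the lesion.

Method 2 has a documented failure mode on concave/imbalanced shapes
(points collapsing together, regions escaping the lesion); it is detected
and reported, never silently repaired — method 3 is the fix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ._errors import DegenerateContractionError, ParameterError
from .boundary import BoundaryPath, CentroidPoint
from .maskprep import LesionMask

logger = logging.getLogger(__name__)

#: circle radii (pixels) used throughout: the four sampling scales.
DEFAULT_RADII: Tuple[int, ...] = (5, 7, 10, 15)


@dataclass(frozen=True)
class CircleSpec:
    center: Tuple[float, float]  # (x, y) sub-pixel
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"circle radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class RegionMask:
    bits: np.ndarray
    provenance: str  # method1_circle | method2_polygon | method3_polygon
    center_index: int

    @property
    def area(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class InnerBoundary:
    """Closed sub-pixel path of the contracted (shadow) border."""

    points: np.ndarray  # K x 2 array of (x, y)
    method: str  # vector_shift | dynamic_scale
    r: float
    s: Optional[float] = None  # scale factor, dynamic_scale only
    degenerate: bool = False

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, i: int) -> Tuple[float, float]:
        return tuple(self.points[i])

    def as_xy(self) -> np.ndarray:
        return self.points


def spacing_for_radius(r: float) -> int:
    """Inter-center spacing in chain-code steps: 1.5 * r, rounded half-up."""
    return int(np.floor(1.5 * r + 0.5))


def place_centers(path_len: int, r: float) -> List[int]:
    """Center indices 0, k, 2k, ... around the cyclic path (k = 1.5 r)."""
    k = spacing_for_radius(r)
    if path_len < k:
        warnings.warn(
            f"path of length {path_len} shorter than spacing {k}; single center",
            stacklevel=2,
        )
        return [0]
    return list(range(0, path_len, k))


def rasterize_circle(
    center: Tuple[float, float], radius: float, shape: Tuple[int, int]
) -> np.ndarray:
    """Boolean disk: pixel (row, col) included iff its center lies in the disk."""
    cx, cy = center
    h, w = shape
    r0 = max(0, int(np.floor(cy - radius)))
    r1 = min(h, int(np.ceil(cy + radius)) + 1)
    c0 = max(0, int(np.floor(cx - radius)))
    c1 = min(w, int(np.ceil(cx + radius)) + 1)
    out = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    out[r0:r1, c0:c1] = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2
    return out


def method1_regions(
    m: LesionMask, path: BoundaryPath, r: float
) -> List[RegionMask]:
    """Full disks on the outer boundary, clipped only to image bounds."""
    shape = (m.height, m.width)
    regions = []
    pts = path.as_xy()
    for idx in place_centers(len(path), r):
        disk = rasterize_circle(tuple(pts[idx]), r, shape)
        if disk.any():
            regions.append(RegionMask(disk, "method1_circle", idx))
    return regions


def method2_inner_boundary(
    path: BoundaryPath, c: CentroidPoint, r: float
) -> InnerBoundary:
    """Shift every boundary point ``r`` pixels toward the centroid.

    Raises DegenerateContractionError when any point lies closer than ``r``
    to the centroid. Points at distance exactly ``r`` map onto the centroid
    and, like near-collapses detected by a minimum pairwise-spacing check,
    only set the ``degenerate`` flag.
    """
    xy = path.as_xy()
    cvec = c.as_xy()
    diff = cvec[None, :] - xy
    dist = np.hypot(diff[:, 0], diff[:, 1])
    if np.any(dist < r):
        worst = float(dist.min())
        raise DegenerateContractionError(
            f"boundary point at distance {worst:.2f} < r={r} from centroid; "
            "vector-shift contraction is invalid for this shape"
        )
    unit = diff / dist[:, None]
    inner = xy + unit * r

    # Many-to-one collapse detection: points within ~1 px of the centroid
    # after contraction, or distant path positions landing almost on top of
    # each other (fold-over), mark the boundary degenerate.
    degenerate = bool(np.any(dist - r < 1.0))
    if not degenerate and len(inner) > 12:
        tree = cKDTree(inner)
        n = len(inner)
        for i, j in tree.query_pairs(0.5):
            if min(abs(i - j), n - abs(i - j)) > max(6, int(2 * r)):
                degenerate = True
                break
    if degenerate:
        logger.warning(
            "vector-shift contraction degenerate at r=%s: points collapse "
            "toward a single location", r,
        )
    return InnerBoundary(inner, "vector_shift", r, degenerate=degenerate)


def method3_scale_factor(
    start_xy: Tuple[float, float], c: CentroidPoint, r: float
) -> float:
    """s = 1 - r / rho, with rho the centroid distance of the starting point."""
    dx = start_xy[0] - c.x
    dy = start_xy[1] - c.y
    rho = float(np.hypot(dx, dy))
    if rho <= r:
        raise DegenerateContractionError(
            f"starting point at distance {rho:.2f} <= r={r}: lesion too small "
            "for this sampling scale"
        )
    return 1.0 - r / rho


def method3_inner_boundary(
    path: BoundaryPath, c: CentroidPoint, r: float
) -> InnerBoundary:
    """Uniform scaling of the boundary about the centroid.

    All points are scaled by ``s`` (about the origin) and translated by the
    difference between the original and scaled centroids, which is
    equivalent to scaling about the centroid; the starting point moves
    inward exactly ``r``.
    """
    xy = path.as_xy()
    s = method3_scale_factor(tuple(xy[0]), c, r)
    scaled = xy * s
    d = c.as_xy() - scaled.mean(axis=0)  # centroid(x,y) - centroid(x',y')
    inner = scaled + d
    return InnerBoundary(inner, "dynamic_scale", r, s=s)


def intersect_with_lesion(
    circle: CircleSpec, m: LesionMask, *, provenance: str, center_index: int = 0
) -> Optional[RegionMask]:
    """Raster intersection of a disk with the lesion foreground.

    Returns None (with a warning) when the intersection is empty — the
    region is skipped, mirroring the noise-exclusion rule that pixels
    outside the lesion border never enter the statistics.
    """
    disk = rasterize_circle(circle.center, circle.radius, m.bits.shape)
    bits = disk & m.bits
    if not bits.any():
        warnings.warn(
            f"circle at {circle.center} r={circle.radius} misses the lesion; "
            "region skipped",
            stacklevel=2,
        )
        return None
    return RegionMask(bits, provenance, center_index)


def inner_border_regions(
    m: LesionMask,
    path: BoundaryPath,
    c: CentroidPoint,
    r: float,
    method: int,
) -> List[RegionMask]:
    """Disks on the method-2 or method-3 inner border, clipped to the lesion."""
    if method == 2:
        inner = method2_inner_boundary(path, c, r)
        provenance = "method2_polygon"
    elif method == 3:
        inner = method3_inner_boundary(path, c, r)
        provenance = "method3_polygon"
    else:
        raise ParameterError(f"inner-border methods are 2 or 3, got {method}")
    regions: List[RegionMask] = []
    skipped = 0
    for idx in place_centers(len(inner), r):
        reg = intersect_with_lesion(
            CircleSpec(tuple(inner.points[idx]), r), m,
            provenance=provenance, center_index=idx,
        )
        if reg is None:
            skipped += 1
        else:
            regions.append(reg)
    if skipped:
        logger.info("method %d r=%s: skipped %d empty regions", method, r, skipped)
    return regions


def regions_for_method(
    m: LesionMask,
    path: BoundaryPath,
    c: CentroidPoint,
    r: float,
    method: int,
) -> List[RegionMask]:
    """Dispatch: sampling regions for one radius under the chosen method."""
    if method == 1:
        return method1_regions(m, path, r)
    return inner_border_regions(m, path, c, r, method)
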