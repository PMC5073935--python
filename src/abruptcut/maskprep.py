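"""Lesion-mask standardization.

Fixed stage order: complement -> clip margins -> morphological opening ->
keep the central cluster. Every stage after complement only removes
foreground, and the final mask holds exactly one 8-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.morphology import disk

from ._errors import EmptyMaskError, InputError, ParameterError

_N8 = np.ones((3, 3), dtype=bool)
_N4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class LesionMask:
    """A binary H x W grid, 1 = lesion foreground."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits).astype(bool)
        if arr.ndim != 2:
            raise InputError(f"mask must be 2-D, got shape {arr.shape}")
        object.__setattr__(self, "bits", arr)

    @property
    def height(self) -> int:
        return self.bits.shape[0]

    @property
    def width(self) -> int:
        return self.bits.shape[1]

    @property
    def area(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class ClipRect:
    """1-based inclusive pixel bounds of the retained central rectangle."""

    left: int
    right: int
    top: int
    bottom: int

    def __post_init__(self) -> None:
        if not (1 <= self.left < self.right):
            raise ParameterError(f"invalid horizontal bounds {self.left}..{self.right}")
        if not (1 <= self.top < self.bottom):
            raise ParameterError(f"invalid vertical bounds {self.top}..{self.bottom}")


def load_mask(path: str | Path) -> LesionMask:
    """Read a mask from a single-channel PNG/PBM; nonzero = foreground."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read mask {path}: {exc}") from exc
    return LesionMask(arr > 127)


def save_mask(mask: LesionMask, path: str | Path) -> None:
    Image.fromarray((mask.bits.astype(np.uint8)) * 255, mode="L").save(path)


def complement_mask(m: LesionMask) -> LesionMask:
    """Flip every bit (the raw segmenter output marks lesion as background)."""
    return LesionMask(~m.bits)


def compute_clip_rect(
    w: int, h: int, p: float, *, literal_formula: bool = False
) -> ClipRect:
    """Central rectangle keeping all but a ``p``-percent margin per dimension.

    The margin on each side is ``round(dim * p / 200)`` so that a total of
    ``p`` percent of each dimension is clipped, split across the two sides.
    ``literal_formula=True`` switches to the uncorrected published formula
    ``1 + dim / (2 p / 100)``, retained only for comparison; it does not
    produce a usable rectangle for p < 100.
    """
    if not (0 < p < 100):
        raise ParameterError(f"clip percentage must be in (0, 100), got {p}")
    if w < 4 or h < 4:
        raise ParameterError(f"image too small to clip: {w}x{h}")
    if literal_formula:
        mx = w / (2 * (p / 100.0))
        my = h / (2 * (p / 100.0))
        return ClipRect(
            left=int(1 + mx), right=int(w - mx),
            top=int(1 + my), bottom=int(h - my),
        )
    # round-half-up: margins are nonnegative
    mx = int(np.floor(w * p / 200.0 + 0.5))
    my = int(np.floor(h * p / 200.0 + 0.5))
    return ClipRect(left=1 + mx, right=w - mx, top=1 + my, bottom=h - my)


def clip_outside(m: LesionMask, rect: ClipRect) -> LesionMask:
    """Clear all foreground outside the (1-based, inclusive) rectangle."""
    if rect.right > m.width or rect.bottom > m.height:
        raise ParameterError("clip rectangle exceeds mask bounds")
    out = np.zeros_like(m.bits)
    r0, r1 = rect.top - 1, rect.bottom  # to 0-based half-open
    c0, c1 = rect.left - 1, rect.right
    out[r0:r1, c0:c1] = m.bits[r0:r1, c0:c1]
    return LesionMask(out)


def structuring_element(kind: str = "disk", radius: int = 2) -> np.ndarray:
    """N4 cross, N8 square, or a disk of the given radius."""
    if kind == "N4":
        return _N4.copy()
    if kind == "N8":
        return _N8.copy()
    if kind == "disk":
        return disk(radius).astype(bool)
    raise ParameterError(f"unknown structuring element {kind!r}")


def morphological_open(m: LesionMask, struct_el: np.ndarray) -> LesionMask:
    """Opening = dilation of the erosion; removes objects smaller than the element."""
    opened = ndimage.binary_opening(m.bits, structure=struct_el)
    return LesionMask(opened)


def select_central_cluster(m: LesionMask) -> LesionMask:
    """Keep one 8-connected component: the largest whose bounding box meets
    the central ninth of the image, else the one nearest the image center."""
    labels, n = ndimage.label(m.bits, structure=_N8)
    if n == 0:
        raise EmptyMaskError("mask has no foreground component (segmentation failed)")
    if n == 1:
        return LesionMask(m.bits)

    h, w = m.bits.shape
    cr0, cr1 = h / 3.0, 2.0 * h / 3.0
    cc0, cc1 = w / 3.0, 2.0 * w / 3.0
    slices = ndimage.find_objects(labels)
    areas = ndimage.sum_labels(m.bits, labels, index=np.arange(1, n + 1))

    central = []
    for idx, sl in enumerate(slices):
        rs, cs = sl
        if rs.start < cr1 and rs.stop > cr0 and cs.start < cc1 and cs.stop > cc0:
            central.append(idx)
    if central:
        keep = max(central, key=lambda i: areas[i])
    else:
        centers = ndimage.center_of_mass(m.bits, labels, index=np.arange(1, n + 1))
        mid = np.array([h / 2.0, w / 2.0])
        dists = [np.hypot(c[0] - mid[0], c[1] - mid[1]) for c in centers]
        keep = int(np.argmin(dists))
    return LesionMask(labels == keep + 1)


def standardize_mask(
    m: LesionMask,
    *,
    clip_percent: float = 10.0,
    struct_el: np.ndarray | None = None,
    complement: bool = True,
    literal_clip_formula: bool = False,
) -> LesionMask:
    """Full standardization pipeline in the fixed stage order."""
    if complement:
        m = complement_mask(m)
    rect = compute_clip_rect(
        m.width, m.height, clip_percent, literal_formula=literal_clip_formula
    )
    m = clip_outside(m, rect)
    if struct_el is None:
        struct_el = structuring_element("disk", 2)
    m = morphological_open(m, struct_el)
    m = select_central_cluster(m)
    if m.area == 0:
        raise EmptyMaskError("standardization removed all foreground")
    return m


def component_count(m: LesionMask) -> int:
    """Number of 8-connected foreground components."""
    _, n = ndimage.label(m.bits, structure=_N8)
    return int(n)
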