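"""Color-channel decomposition of RGB dermoscopy images.

Every image is expanded into ten scalar channels: gray (``Gra``), the RGB
components (``Red``, ``Gre``, ``Blu``), full-range BT.601 luma/chroma
(``Y``, ``Cb``, ``Cr``) and hexcone HSV (``Hue``, ``Sat``, ``V``).
Downstream texture statistics are computed independently per channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np
from PIL import Image

from ._errors import InputError

logger = logging.getLogger(__name__)

#: Canonical channel order used everywhere (feature naming, reports).
CHANNEL_LABELS: Tuple[str, ...] = (
    "Gra", "Red", "Gre", "Blu", "Y", "Cb", "Cr", "Hue", "Sat", "V",
)

#: Declared value range per channel, used for quantization and rescaling.
CHANNEL_RANGES: Mapping[str, Tuple[float, float]] = {
    "Gra": (0.0, 255.0),
    "Red": (0.0, 255.0),
    "Gre": (0.0, 255.0),
    "Blu": (0.0, 255.0),
    "Y": (0.0, 255.0),
    "Cb": (0.0, 255.0),
    "Cr": (0.0, 255.0),
    "Hue": (0.0, 360.0),
    "Sat": (0.0, 1.0),
    "V": (0.0, 255.0),
}

# Full-range BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RGBImage:
    """An H x W x 3 uint8 raster."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError(f"expected H x W x 3 pixel array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ChannelImage:
    """One scalar channel plus its declared value range."""

    values: np.ndarray
    channel_label: str
    value_range: Tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def unit_scaled(self) -> np.ndarray:
        """Values linearly rescaled to [0, 1] by the declared range."""
        lo, hi = self.value_range
        return (self.values - lo) / (hi - lo)


@dataclass(frozen=True)
class ChannelStack:
    """The ten channels of one image, keyed by label."""

    channels: Dict[str, ChannelImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CHANNEL_LABELS) - set(self.channels)
        if missing:
            raise ValueError(f"channel stack missing labels: {sorted(missing)}")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent channel shapes: {shapes}")

    def __getitem__(self, label: str) -> ChannelImage:
        return self.channels[label]

    def __iter__(self) -> Iterator[str]:
        return iter(CHANNEL_LABELS)

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape


def load_image(path: str | Path) -> RGBImage:
    """Read a raster image from disk as 24-bit RGB.

    Grayscale input is replicated across R, G, B; an alpha channel is
    dropped with a warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode != "RGB":
                logger.warning("converting %s from mode %s to RGB", path.name, im.mode)
                warnings.warn(
                    f"{path.name}: mode {im.mode} converted to RGB (alpha dropped)",
                    stacklevel=2,
                )
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    return RGBImage(arr)


def rgb_to_ycbcr(rgb: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-range BT.601 conversion; returns float (Y, Cb, Cr), chroma offset 128."""
    r = rgb[..., 0].astype(np.float64)
    g = rgb[..., 1].astype(np.float64)
    b = rgb[..., 2].astype(np.float64)
    y = _LUMA[0] * r + _LUMA[1] * g + _LUMA[2] * b
    cb = 128.0 - 0.168735892 * r - 0.331264108 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418687589 * g - 0.081312411 * b
    return y, cb, cr


def rgb_to_hsv(rgb: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hexcone HSV: Hue in [0, 360), Sat in [0, 1], V = max(R,G,B) in [0, 255].

    Achromatic pixels (max == min) get Hue = 0 so no NaN reaches the GLCM.
    """
    rgbf = rgb.astype(np.float64)
    r, g, b = rgbf[..., 0], rgbf[..., 1], rgbf[..., 2]
    v = rgbf.max(axis=-1)
    mn = rgbf.min(axis=-1)
    delta = v - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(v > 0, delta / v, 0.0)
        hue = np.zeros_like(v)
        chromatic = delta > 0
        rc = np.where(chromatic, (v - r) / np.where(delta == 0, 1, delta), 0.0)
        gc = np.where(chromatic, (v - g) / np.where(delta == 0, 1, delta), 0.0)
        bc = np.where(chromatic, (v - b) / np.where(delta == 0, 1, delta), 0.0)
    hue = np.where(r == v, bc - gc, hue)
    hue = np.where((g == v) & (r != v), 2.0 + rc - bc, hue)
    hue = np.where((b == v) & (r != v) & (g != v), 4.0 + gc - rc, hue)
    hue = (hue * 60.0) % 360.0
    hue = np.where(chromatic, hue, 0.0)
    return hue, sat, v


def extract_channels(img: RGBImage) -> ChannelStack:
    """Decompose an RGB image into the ten scalar channels."""
    rgb = img.pixels
    y, cb, cr = rgb_to_ycbcr(rgb)
    hue, sat, v = rgb_to_hsv(rgb)
    values = {
        "Gra": y,  # gray and luma share the BT.601 weights
        "Red": rgb[..., 0].astype(np.float64),
        "Gre": rgb[..., 1].astype(np.float64),
        "Blu": rgb[..., 2].astype(np.float64),
        "Y": y,
        "Cb": cb,
        "Cr": cr,
        "Hue": hue,
        "Sat": sat,
        "V": v,
    }
    channels = {
        label: ChannelImage(values[label], label, tuple(CHANNEL_RANGES[label]))
        for label in CHANNEL_LABELS
    }
    return ChannelStack(channels)


def save_channels(stack: ChannelStack, out_dir: str | Path, stem: str) -> None:
    """Debug export: one 8-bit PNG per channel, rescaled by declared range."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label in stack:
        chan = stack[label]
        u8 = np.clip(chan.unit_scaled() * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(u8, mode="L").save(out_dir / f"{stem}_{label}.png")
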