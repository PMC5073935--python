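"""Synthetic dermoscopy-like image generator.

Stands in for the unavailable clinical dataset: roughly centered lesions,
darker than the surrounding skin, whose border sharpness is controlled per
angular sector ("virtual pie"). The radial intensity profile across the
border is a sigmoid of the signed distance with a per-sector width tau;
small tau = abrupt pigment cutoff. A sample is labeled malignant iff at
least one sector's width is at or below the abrupt threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._errors import ParameterError
from .channels import RGBImage
from .maskprep import LesionMask

#: default per-sector edge widths (pixels)
TAU_ABRUPT_THRESHOLD = 2.0
GRADUAL_RANGE = (6.0, 12.0)
ABRUPT_RANGE = (0.8, 2.0)

DEFAULT_SKIN = (225, 185, 205)
DEFAULT_LESION = (110, 70, 30)


@dataclass(frozen=True)
class SyntheticLesionSpec:
    image_size: Tuple[int, int] = (256, 256)  # (H, W)
    base_radius: float = 64.0
    harmonics: Tuple[Tuple[int, float, float], ...] = ()  # (k, amplitude, phase)
    n_sectors: int = 8
    edge_width: Tuple[float, ...] = (8.0,) * 8  # tau per sector
    gradual_width: Optional[Tuple[float, ...]] = None  # fallback for non-abrupt channels
    lesion_color: Tuple[int, int, int] = DEFAULT_LESION
    skin_color: Tuple[int, int, int] = DEFAULT_SKIN
    noise_sigma: float | Tuple[float, float, float] = 4.0
    seed: int = 0
    abrupt_channels: Tuple[int, ...] = (0, 1, 2)  # RGB indices expressing sector tau
    tau_abrupt: float = TAU_ABRUPT_THRESHOLD

    def __post_init__(self) -> None:
        h, w = self.image_size
        max_r = self.base_radius * (1.0 + sum(abs(a) for _, a, _ in self.harmonics))
        if max_r >= min(h, w) / 2.0 - 16.0:
            raise ParameterError(
                f"lesion radius {max_r:.1f} too large for image {h}x{w}"
            )
        if len(self.edge_width) != self.n_sectors:
            raise ParameterError("edge_width must have one value per sector")
        if any(t <= 0 for t in self.edge_width):
            raise ParameterError("sector edge widths must be positive")

    @property
    def label(self) -> str:
        """Malignant iff at least one sector has an abrupt cutoff."""
        return (
            "malignant"
            if min(self.edge_width) <= self.tau_abrupt
            else "benign"
        )


@dataclass(frozen=True)
class LabeledSample:
    image: RGBImage
    mask: LesionMask
    label: str
    spec: SyntheticLesionSpec
    image_id: str = ""


def _border_radius(theta: np.ndarray, spec: SyntheticLesionSpec) -> np.ndarray:
    r = np.full_like(theta, spec.base_radius)
    for k, a, phi in spec.harmonics:
        r += spec.base_radius * a * np.cos(k * theta + phi)
    return r


def signed_distance(spec: SyntheticLesionSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Radial signed distance to the harmonic border; positive outside."""
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    rho = np.hypot(rows, cols)
    theta = np.mod(np.arctan2(rows, cols), 2.0 * np.pi)
    return rho - _border_radius(theta, spec), theta


def _sector_tau(theta: np.ndarray, widths: Sequence[float], n_sectors: int) -> np.ndarray:
    sector = np.minimum(
        (theta / (2.0 * np.pi) * n_sectors).astype(int), n_sectors - 1
    )
    return np.asarray(widths, dtype=np.float64)[sector]


def generate_lesion(spec: SyntheticLesionSpec) -> LabeledSample:
    """Render one sample: sigmoid border profile + Gaussian noise.

    Channels not listed in ``abrupt_channels`` use the gradual fallback
    widths, so the abrupt-cutoff contrast can be injected into a subset of
    the RGB channels (e.g. blue only).
    """
    d, theta = signed_distance(spec)
    tau_map = _sector_tau(theta, spec.edge_width, spec.n_sectors)
    if spec.gradual_width is not None:
        fallback = _sector_tau(theta, spec.gradual_width, spec.n_sectors)
    else:
        fallback = tau_map

    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    img = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        tau = tau_map if c in spec.abrupt_channels else fallback
        # sigmoid(-d/tau): 1 deep inside the lesion, 0 far outside
        profile = 1.0 / (1.0 + np.exp(np.clip(d / tau, -60.0, 60.0)))
        img[..., c] = (
            spec.skin_color[c]
            + (spec.lesion_color[c] - spec.skin_color[c]) * profile
        )
    sigma = np.broadcast_to(np.asarray(spec.noise_sigma, dtype=float), (3,))
    if np.any(sigma > 0):
        img += rng.normal(0.0, 1.0, size=img.shape) * sigma

    image = RGBImage(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    mask = LesionMask(d < 0)
    return LabeledSample(image, mask, spec.label, spec)


def _random_harmonics(rng: np.random.Generator) -> Tuple[Tuple[int, float, float], ...]:
    ks = rng.choice(np.arange(2, 6), size=2, replace=False)
    return tuple(
        (int(k), float(rng.uniform(0.02, 0.07)), float(rng.uniform(0, 2 * np.pi)))
        for k in ks
    )


def make_spec(
    rng: np.random.Generator,
    malignant: bool,
    *,
    image_size: Tuple[int, int] = (256, 256),
    radius_range: Optional[Tuple[float, float]] = None,
    gradual_range: Tuple[float, float] = GRADUAL_RANGE,
    abrupt_range: Tuple[float, float] = ABRUPT_RANGE,
    n_sectors: int = 8,
    abrupt_channels: Tuple[int, ...] = (0, 1, 2),
    noise_sigma: float = 4.0,
) -> SyntheticLesionSpec:
    """Draw one randomized lesion spec of the requested class."""
    if radius_range is None:
        half = min(image_size) / 2.0
        radius_range = (0.41 * half, 0.56 * half)
    gradual = rng.uniform(*gradual_range, size=n_sectors)
    widths = gradual.copy()
    if malignant:
        n_abrupt = int(rng.integers(1, 4))
        idx = rng.choice(n_sectors, size=n_abrupt, replace=False)
        widths[idx] = rng.uniform(*abrupt_range, size=n_abrupt)
    return SyntheticLesionSpec(
        image_size=image_size,
        base_radius=float(rng.uniform(*radius_range)),
        harmonics=_random_harmonics(rng),
        n_sectors=n_sectors,
        edge_width=tuple(widths),
        gradual_width=tuple(gradual),
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
        abrupt_channels=abrupt_channels,
    )


def generate_dataset(
    n_benign: int,
    n_malignant: int,
    *,
    seed: int = 1,
    image_size: Tuple[int, int] = (256, 256),
    radius_range: Optional[Tuple[float, float]] = None,
    abrupt_channels: Tuple[int, ...] = (0, 1, 2),
    noise_sigma: float = 4.0,
) -> List[LabeledSample]:
    """Seeded benchmark dataset; benign samples first, then malignant."""
    if n_benign < 0 or n_malignant < 0 or n_benign + n_malignant < 1:
        raise ParameterError("need at least one sample")
    rng = np.random.default_rng(seed)
    samples: List[LabeledSample] = []
    for i in range(n_benign + n_malignant):
        malignant = i >= n_benign
        spec = make_spec(
            rng, malignant,
            image_size=image_size, radius_range=radius_range,
            abrupt_channels=abrupt_channels, noise_sigma=noise_sigma,
        )
        sample = generate_lesion(spec)
        cls = "mal" if malignant else "ben"
        samples.append(replace_id(sample, f"{cls}_{i:03d}"))
    return samples


#: Colors/noise for the blue-channel signal-recovery benchmark. The red and
#: green contrasts run opposite to blue and carry extra noise, so every
#: mixture channel (Cb, Y, Gra, ...) sees an inflated gradual baseline and a
#: degraded abrupt signal relative to the pure blue channel.
BLUE_INJECTION_LESION = (210, 195, 30)
BLUE_INJECTION_SKIN = (130, 115, 205)
BLUE_INJECTION_NOISE = (8.0, 8.0, 3.0)


def blue_injection_dataset(
    n_benign: int,
    n_malignant: int,
    *,
    seed: int = 1,
    image_size: Tuple[int, int] = (192, 192),
    radius_range: Optional[Tuple[float, float]] = None,
) -> List[LabeledSample]:
    """Dataset with abrupt-cutoff contrast injected into the blue channel only."""
    rng = np.random.default_rng(seed)
    samples: List[LabeledSample] = []
    for i in range(n_benign + n_malignant):
        malignant = i >= n_benign
        spec = make_spec(
            rng, malignant, image_size=image_size, radius_range=radius_range,
            abrupt_channels=(2,),
        )
        spec = replace(
            spec,
            lesion_color=BLUE_INJECTION_LESION,
            skin_color=BLUE_INJECTION_SKIN,
            noise_sigma=BLUE_INJECTION_NOISE,
        )
        cls = "mal" if malignant else "ben"
        samples.append(replace_id(generate_lesion(spec), f"{cls}_{i:03d}"))
    return samples


def replace_id(sample: LabeledSample, image_id: str) -> LabeledSample:
    return LabeledSample(sample.image, sample.mask, sample.label, sample.spec, image_id)


def write_dataset(samples: Sequence[LabeledSample], out_dir: str | Path) -> None:
    """Write images, masks and labels.csv (PNG + CSV)."""
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    lines = ["image_id,label"]
    for s in samples:
        Image.fromarray(s.image.pixels).save(out_dir / "images" / f"{s.image_id}.png")
        Image.fromarray(s.mask.bits.astype(np.uint8) * 255, mode="L").save(
            out_dir / "masks" / f"{s.image_id}_mask.png"
        )
        lines.append(f"{s.image_id},{s.label}")
    (out_dir / "labels.csv").write_text("\n".join(lines) + "\n")
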