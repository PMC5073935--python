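"""Per-image feature vectors and the dataset feature table.

Each image yields 240 features: 10 channels x 4 radii x {average, minimum}
of {homogeneity, mean, std} over all peripheral regions of that radius.
Names render as ``<channel>-<radius>-<agg><stat>``, e.g. ``Gre-5-AH`` is
the average homogeneity of the green channel at radius 5 and ``Blu-10-MM``
the minimum mean of the blue channel at radius 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import FeatureExtractionError, ParameterError
from .boundary import centroid, trace_boundary
from .channels import CHANNEL_LABELS, ChannelStack
from .glcm import GLCMSpec, compute_glcm, homogeneity, normalize_glcm, quantize
from .maskprep import LesionMask
from .sampling import DEFAULT_RADII, RegionMask, regions_for_method

AGGS = ("A", "M")  # average, minimum
STATS = ("H", "M", "S")  # homogeneity, mean, std


@dataclass(frozen=True, order=True)
class FeatureName:
    channel: str
    radius: int
    agg: str  # A | M
    stat: str  # H | M | S

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_LABELS:
            raise ParameterError(f"unknown channel {self.channel!r}")
        if self.agg not in AGGS or self.stat not in STATS:
            raise ParameterError(f"bad aggregate/stat {self.agg}{self.stat}")

    def render(self) -> str:
        return f"{self.channel}-{self.radius}-{self.agg}{self.stat}"

    @classmethod
    def parse(cls, text: str) -> "FeatureName":
        chan, radius, aggstat = text.split("-")
        return cls(chan, int(radius), aggstat[0], aggstat[1])


def feature_names(
    channels: Sequence[str] = CHANNEL_LABELS,
    radii: Sequence[int] = DEFAULT_RADII,
) -> List[str]:
    """Rendered names in canonical order: channel, radius, stat-pair."""
    names = []
    for ch in channels:
        for r in radii:
            for stat in STATS:
                for agg in AGGS:
                    names.append(FeatureName(ch, r, agg, stat).render())
    return names


def extract_features(
    stack: ChannelStack,
    m: LesionMask,
    *,
    method: int = 3,
    radii: Sequence[int] = DEFAULT_RADII,
    channels: Sequence[str] = CHANNEL_LABELS,
    glcm_spec: GLCMSpec = GLCMSpec(),
    homogeneity_mode: str = "standard",
) -> Dict[str, float]:
    """Compute the per-image feature mapping (rendered name -> value).

    Regions whose lesion intersection is empty are excluded from both the
    average and the minimum; if every region at some radius is skipped a
    FeatureExtractionError names that radius.
    """
    if stack.shape != (m.height, m.width):
        raise ParameterError("channel stack and mask dimensions differ")
    path = trace_boundary(m)
    cen = centroid(m)

    # geometry is channel-independent: build regions once per radius
    regions_by_radius: Dict[int, List[RegionMask]] = {}
    for r in radii:
        regs = regions_for_method(m, path, cen, r, method)
        if not regs:
            raise FeatureExtractionError(
                f"no valid sampling region at radius {r} (lesion too small?)"
            )
        regions_by_radius[r] = regs

    out: Dict[str, float] = {}
    for label in channels:
        chan = stack[label]
        lo, hi = glcm_spec.quantize_range or chan.value_range
        quantized = quantize(chan.values, glcm_spec.levels, lo, hi)
        unit = chan.unit_scaled()
        for r in radii:
            homs, means, stds = [], [], []
            for reg in regions_by_radius[r]:
                co = compute_glcm(quantized, reg.bits, glcm_spec, prequantized=True)
                if co.n_pairs > 0:
                    h = homogeneity(normalize_glcm(co, "pair_count"),
                                    homogeneity_mode)
                else:
                    h = 1.0  # degenerate sliver: single-level trivial texture
                px = unit[reg.bits]
                homs.append(h)
                means.append(float(px.mean()))
                stds.append(float(px.std()))
            stats = {"H": homs, "M": means, "S": stds}
            for stat, vals in stats.items():
                arr = np.asarray(vals)
                out[FeatureName(label, r, "A", stat).render()] = float(arr.mean())
                out[FeatureName(label, r, "M", stat).render()] = float(arr.min())
    return out


@dataclass
class FeatureTable:
    """Rows = images, feature columns + a label column."""

    frame: pd.DataFrame  # indexed by image_id; feature columns only
    labels: pd.Series  # image_id -> 'malignant' | 'benign'
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.frame.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.frame.index)
        if self.labels.isna().any():
            raise ParameterError("missing label for some image_id")

    @property
    def n_images(self) -> int:
        return len(self.frame)

    @property
    def feature_columns(self) -> List[str]:
        return list(self.frame.columns)

    def y(self) -> np.ndarray:
        """Binary target: 1 = malignant, 0 = benign."""
        return (self.labels == "malignant").to_numpy(dtype=int)

    def X(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        df = self.frame.copy()
        df.insert(0, "label", self.labels)
        df.to_csv(path, index_label="image_id")

    @classmethod
    def from_csv(cls, path, *, normalized: bool = False) -> "FeatureTable":
        df = pd.read_csv(path, index_col="image_id")
        labels = df.pop("label")
        return cls(df, labels, normalized=normalized)


def build_table(
    rows: Dict[str, Dict[str, float]],
    labels: Dict[str, str],
    columns: Optional[Sequence[str]] = None,
) -> FeatureTable:
    """Assemble per-image feature mappings into a FeatureTable."""
    frame = pd.DataFrame.from_dict(rows, orient="index")
    if columns is not None:
        frame = frame[list(columns)]
    frame.index.name = "image_id"
    return FeatureTable(frame, pd.Series(labels, name="label"))


def extract_dataset_features(
    samples,
    *,
    method: int = 3,
    radii: Sequence[int] = DEFAULT_RADII,
    channels: Sequence[str] = CHANNEL_LABELS,
    glcm_spec: GLCMSpec = GLCMSpec(),
    homogeneity_mode: str = "standard",
) -> FeatureTable:
    """Run per-image extraction over labeled samples and assemble the table.

    ``samples`` is any iterable of objects with ``image`` (RGBImage),
    ``mask`` (LesionMask), ``image_id`` and ``label`` attributes.
    """
    from .channels import extract_channels

    rows: Dict[str, Dict[str, float]] = {}
    labels: Dict[str, str] = {}
    for i, s in enumerate(samples):
        image_id = s.image_id or f"img_{i:03d}"
        rows[image_id] = extract_features(
            extract_channels(s.image), s.mask,
            method=method, radii=radii, channels=channels,
            glcm_spec=glcm_spec, homogeneity_mode=homogeneity_mode,
        )
        labels[image_id] = s.label
    return build_table(rows, labels, columns=feature_names(channels, radii))


def subset_channels(t: FeatureTable, channels: Iterable[str]) -> FeatureTable:
    """Keep only the feature columns of the given channels (24 each)."""
    channels = list(channels)
    unknown = set(channels) - set(CHANNEL_LABELS)
    if unknown:
        raise ParameterError(f"unknown channel labels: {sorted(unknown)}")
    keep = [c for c in t.frame.columns if c.split("-")[0] in channels]
    return FeatureTable(t.frame[keep].copy(), t.labels.copy(),
                        normalized=t.normalized)


def normalize_table(t: FeatureTable) -> FeatureTable:
    """Per-column linear map onto [-1, 1]; constant columns map to 0."""
    if t.n_images < 2:
        raise ParameterError("normalization needs at least 2 rows")
    frame = normalize_like(t.frame, t.frame)
    return FeatureTable(frame, t.labels.copy(), normalized=True)


def normalize_like(frame: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Scale ``frame`` to [-1, 1] using column min/max taken from ``reference``.

    Used to fit the normalization on a training fold and apply it to a held
    out fold without leakage.
    """
    lo = reference.min(axis=0)
    hi = reference.max(axis=0)
    span = hi - lo
    constant = span == 0
    span = span.where(~constant, 1.0)
    out = 2.0 * (frame - lo) / span - 1.0
    out.loc[:, constant] = 0.0
    return out
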