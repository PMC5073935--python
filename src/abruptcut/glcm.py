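"""Gray-level co-occurrence matrices and region texture statistics.

The co-occurrence count for offset (dx, dy) is

    C(i, j) = #{ (p, q) : I(p, q) = i  and  I(p + dy_row, q + dx_col) = j }

computed over a masked region. Two pairing conventions are supported:

``both_in_region``
    only pairs with *both* pixels inside the region mask are counted
    (background is treated as noise and excluded);
``literal_product``
    the channel is multiplied elementwise by the 0/1 mask over the region
    bounding box first, so background contributes zero-intensity pixels —
    the published pipeline's element-by-element multiplication behavior.

Homogeneity likewise has two modes: ``standard`` applies the usual
1/(1+|i-j|) closeness weight; ``paper_literal`` omits the weight (in which
case any probability-normalized matrix sums to 1, a degenerate constant —
kept only for comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._errors import EmptyRegionError, ParameterError
from .channels import ChannelImage


@dataclass(frozen=True)
class GLCMSpec:
    """Offset, quantization and pairing convention for one GLCM."""

    dx: int = 1
    dy: int = 0
    levels: int = 8
    quantize_range: Optional[Tuple[float, float]] = None
    pair_mode: str = "both_in_region"

    def __post_init__(self) -> None:
        if (self.dx, self.dy) == (0, 0):
            raise ParameterError("GLCM offset must be nonzero")
        if self.levels < 2:
            raise ParameterError("GLCM needs at least 2 gray levels")
        if self.pair_mode not in ("both_in_region", "literal_product"):
            raise ParameterError(f"unknown pair_mode {self.pair_mode!r}")


@dataclass(frozen=True)
class CoocMatrix:
    counts: np.ndarray
    spec: GLCMSpec
    n_pairs: int
    region_dims: Tuple[int, int]  # (M cols, N rows) of the region bounding box


def quantize(values: np.ndarray, levels: int, lo: float, hi: float) -> np.ndarray:
    """Linear binning of [lo, hi] onto integer levels 0..levels-1."""
    if hi <= lo:
        raise ParameterError(f"bad quantize range [{lo}, {hi}]")
    q = np.floor((np.asarray(values, dtype=np.float64) - lo) / (hi - lo) * levels)
    return np.clip(q, 0, levels - 1).astype(np.intp)


def compute_glcm(
    chan: ChannelImage | np.ndarray,
    region: np.ndarray,
    spec: GLCMSpec,
    *,
    prequantized: bool = False,
) -> CoocMatrix:
    """Count co-occurring quantized intensity pairs inside a masked region.

    ``chan`` may be a ChannelImage (quantized by its declared range unless
    ``spec.quantize_range`` overrides it) or a raw integer array with
    ``prequantized=True`` (values already in 0..levels-1, as in small
    worked examples).
    """
    region = np.asarray(region).astype(bool)
    if region.ndim != 2 or not region.any():
        raise EmptyRegionError("GLCM requested over an empty region")

    if prequantized:
        img = np.asarray(chan, dtype=np.intp)
        if img.min() < 0 or img.max() >= spec.levels:
            raise ParameterError("prequantized values outside 0..levels-1")
    else:
        if isinstance(chan, ChannelImage):
            lo, hi = spec.quantize_range or chan.value_range
            values = chan.values
        else:
            if spec.quantize_range is None:
                raise ParameterError("raw arrays need an explicit quantize_range")
            lo, hi = spec.quantize_range
            values = np.asarray(chan, dtype=np.float64)
        img = quantize(values, spec.levels, lo, hi)
    if img.shape != region.shape:
        raise ParameterError("channel and region shapes differ")

    # crop to the region bounding box
    rows, cols = np.nonzero(region)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub = img[r0:r1, c0:c1]
    subm = region[r0:r1, c0:c1]
    n_rows, n_cols = sub.shape

    dr, dc = spec.dy, spec.dx  # dy shifts rows, dx shifts columns
    if spec.pair_mode == "literal_product":
        sub = sub * subm  # zero out background inside the bounding box
        pair_ok = np.ones_like(subm)
    else:
        pair_ok = subm

    # source window such that (r+dr, c+dc) stays inside the bounding box
    rs0, rs1 = max(0, -dr), min(n_rows, n_rows - dr)
    cs0, cs1 = max(0, -dc), min(n_cols, n_cols - dc)
    L = spec.levels
    counts = np.zeros((L, L), dtype=np.int64)
    if rs1 <= rs0 or cs1 <= cs0:
        warnings.warn("region thinner than the GLCM offset: zero-pair matrix",
                      stacklevel=2)
        return CoocMatrix(counts, spec, 0, (n_cols, n_rows))

    a = sub[rs0:rs1, cs0:cs1]
    b = sub[rs0 + dr:rs1 + dr, cs0 + dc:cs1 + dc]
    ok = pair_ok[rs0:rs1, cs0:cs1] & pair_ok[rs0 + dr:rs1 + dr, cs0 + dc:cs1 + dc]
    flat = a[ok] * L + b[ok]
    if flat.size:
        counts = np.bincount(flat, minlength=L * L).reshape(L, L).astype(np.int64)
    n_pairs = int(ok.sum())
    if n_pairs == 0:
        warnings.warn("no valid pixel pairs in region for GLCM offset", stacklevel=2)
    return CoocMatrix(counts, spec, n_pairs, (n_cols, n_rows))


def normalize_glcm(
    c: CoocMatrix,
    denom_mode: str = "pair_count",
    *,
    dims: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Convert counts to a probability-like matrix.

    ``pair_count`` divides by the number of counted pairs (entries sum to
    1). ``paper_dims`` divides by (M - dx)(N - dy) with (M, N) taken from
    the region bounding box, or from ``dims`` when the published dimensions
    differ from the actual array (as in the printed worked example).
    """
    if denom_mode == "pair_count":
        if c.n_pairs == 0:
            raise ParameterError("cannot normalize a zero-pair matrix")
        return c.counts / float(c.n_pairs)
    if denom_mode == "paper_dims":
        m, n = dims if dims is not None else c.region_dims
        denom = (m - c.spec.dx) * (n - c.spec.dy)
        if denom <= 0:
            raise ParameterError(f"non-positive denominator ({m}-dx)({n}-dy)")
        return c.counts / float(denom)
    raise ParameterError(f"unknown denom_mode {denom_mode!r}")


def homogeneity(p: np.ndarray, mode: str = "standard") -> float:
    """GLCM homogeneity of a probability matrix.

    ``standard``: sum of p(i,j) / (1 + |i-j|).  ``paper_literal``: plain sum
    of p(i,j) (degenerate under probability normalization).
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ParameterError("homogeneity expects a square matrix")
    if mode == "paper_literal":
        return float(p.sum())
    if mode != "standard":
        raise ParameterError(f"unknown homogeneity mode {mode!r}")
    idx = np.arange(p.shape[0])
    weights = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    return float((p * weights).sum())


def region_mean_std(
    chan: ChannelImage | np.ndarray, region: np.ndarray
) -> Tuple[float, float]:
    """Mean and population std over region pixels, on [0, 1]-scaled values."""
    region = np.asarray(region).astype(bool)
    if not region.any():
        raise EmptyRegionError("mean/std requested over an empty region")
    if isinstance(chan, ChannelImage):
        values = chan.unit_scaled()
    else:
        values = np.asarray(chan, dtype=np.float64)
    px = values[region]
    return float(px.mean()), float(px.std())


def region_stats(
    chan: ChannelImage,
    region: np.ndarray,
    spec: GLCMSpec,
    *,
    homogeneity_mode: str = "standard",
    quantized: Optional[np.ndarray] = None,
    unit_values: Optional[np.ndarray] = None,
) -> Tuple[float, float, float]:
    """(homogeneity, mean, std) for one region.

    ``quantized``/``unit_values`` allow precomputed whole-image arrays to be
    reused across many regions of the same channel.
    """
    region = np.asarray(region).astype(bool)
    if not region.any():
        raise EmptyRegionError("statistics requested over an empty region")
    if quantized is None:
        co = compute_glcm(chan, region, spec)
    else:
        co = compute_glcm(quantized, region, spec, prequantized=True)
    if co.n_pairs > 0:
        h = homogeneity(normalize_glcm(co, "pair_count"), homogeneity_mode)
    else:
        h = 1.0  # single-pixel-thin region: trivially uniform
    if unit_values is None:
        mean, std = region_mean_std(chan, region)
    else:
        px = unit_values[region]
        mean, std = float(px.mean()), float(px.std())
    return h, mean, std
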