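"""Filtering and rendering of per-pixel gain maps.

Two complementary segmentation rules operate on a gain map: the zero-
stability mask keeps pixels whose exchange left the entropy unchanged
(time-stable content), while the extreme masks pick the most positive /
most negative gains, which localise a moving object in the first and the
following frame respectively.  Also provides the 8-bit rendering of gain
maps and the least-information-loss bit-depth reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequence import FrameSequence, PDGMap

__all__ = [
    "SegmentationMask",
    "stability_mask",
    "extreme_mask",
    "render_map",
    "render_color",
    "lil_convert",
]


@dataclass(frozen=True)
class SegmentationMask:
    mask: np.ndarray
    rule: str
    parameter: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


def stability_mask(pmap: PDGMap, tol: float = 0.0) -> SegmentationMask:
    """Pixels with ``|Omega| <= tol``; ``tol=0`` keeps exact zeros only
    (unchanged pixels and balanced exchanges)."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    mask = np.abs(pmap.values) <= tol
    return SegmentationMask(mask=mask, rule="zero_stability", parameter=float(tol))


def extreme_mask(
    pmap: PDGMap,
    fraction: float,
    side: str = "top",
    threshold: float | None = None,
) -> SegmentationMask:
    """The given fraction of pixels with the most positive (``top``) or most
    negative (``bottom``) gain.

    Only strictly signed pixels qualify, so an all-zero map yields empty
    masks; ties at the cut value are all included (the mask may exceed the
    nominal fraction).  ``threshold`` switches to an absolute Omega cutoff
    (``>= threshold`` for top, ``<= threshold`` for bottom).
    """
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    values = pmap.values
    rule = f"{side}_extreme"
    if threshold is not None:
        mask = values >= threshold if side == "top" else values <= threshold
        return SegmentationMask(mask=mask, rule=rule, parameter=float(threshold))
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return SegmentationMask(
            mask=np.ones_like(values, dtype=bool), rule=rule, parameter=1.0
        )
    signed = values > 0 if side == "top" else values < 0
    n_target = math.ceil(fraction * values.size)
    candidates = values[signed]
    if candidates.size == 0:
        mask = np.zeros_like(values, dtype=bool)
        return SegmentationMask(mask=mask, rule=rule, parameter=float(fraction))
    ordered = np.sort(candidates)
    if side == "top":
        cut = ordered[max(0, candidates.size - n_target)]
        mask = signed & (values >= cut)
    else:
        cut = ordered[min(candidates.size - 1, n_target - 1)]
        mask = signed & (values <= cut)
    return SegmentationMask(mask=mask, rule=rule, parameter=float(fraction))


def render_map(pmap: PDGMap) -> np.ndarray:
    """8-bit rendering: symmetric linear map of [-M, +M] to [0, 255].

    ``M = max |Omega|``; zero gain renders to the 128 midpoint (uniform
    mid-gray for an all-zero map) and the rendering is invariant to positive
    rescaling of the map.
    """
    values = pmap.values
    if not np.all(np.isfinite(values)):
        raise ValueError("gain map contains non-finite values")
    m = float(np.max(np.abs(values)))
    if m == 0.0:
        return np.full(values.shape, 128, dtype=np.uint8)
    scaled = np.floor(128.0 + (values / m) * 127.5)
    return np.clip(scaled, 0, 255).astype(np.uint8)


def render_color(pmap: PDGMap) -> np.ndarray:
    """Diverging preview: negative gains blue, positive red, zero gray."""
    gray = render_map(pmap).astype(np.float64) / 255.0  # 0..1, 0.5 = zero
    t = 2.0 * gray - 1.0  # -1..1
    mid = np.array([160.0, 160.0, 160.0])
    red = np.array([200.0, 30.0, 30.0])
    blue = np.array([30.0, 60.0, 200.0])
    out = np.empty(pmap.values.shape + (3,), dtype=np.float64)
    pos = t >= 0
    out[pos] = mid + t[pos, None] * (red - mid)
    out[~pos] = mid + (-t[~pos, None]) * (blue - mid)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def lil_convert(seq: FrameSequence, target_depth: int = 8) -> FrameSequence:
    """Least-information-loss bit-depth reduction of a whole series.

    Builds the pooled intensity histogram over all frames, drops empty bins
    (shifting the occupied levels up into a dense rank order) and linearly
    rescales the ranks onto ``[0, 2**target_depth - 1]``.  Monotone: the
    intensity order of any two pixels is preserved (possibly collapsing).
    """
    if target_depth >= seq.bit_depth:
        raise ValueError("target depth must be smaller than the input depth")
    pooled = np.zeros(seq.n_levels, dtype=np.int64)
    for frame in seq:
        pooled += np.bincount(frame.ravel(), minlength=seq.n_levels)
    occupied = np.flatnonzero(pooled)
    if occupied.size < 2:
        raise ValueError("need at least two occupied intensity levels")
    rank = np.full(seq.n_levels, -1, dtype=np.int64)
    rank[occupied] = np.arange(occupied.size)
    top = 2**target_depth - 1
    lut = rank * top // (occupied.size - 1)  # floor rescale of dense ranks
    frames = tuple(lut[frame].astype(np.uint8 if target_depth == 8 else np.uint16) for frame in seq)
    return FrameSequence(frames=frames, bit_depth=target_depth)
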