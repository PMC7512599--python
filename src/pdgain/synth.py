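"""Seeded synthetic frame sequences with known ground truth.

Stands in for camera/microscopy series in tests and demos: a translating
square (known changed-pixel sets per pair), a symmetric focus stack (known
focal frame), and seeded noise pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .sequence import FrameSequence

__all__ = ["SyntheticSpec", "synth_sequence", "square_position", "focal_index"]

KINDS = ("moving_square", "focus_stack", "noise_pair")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic sequence; fixed seed => identical frames."""

    kind: str
    frames: int = 10
    shape: Tuple[int, int] = (64, 64)
    bit_depth: int = 8
    background: int = 16
    foreground: int = 200
    # moving_square
    square_size: int = 12
    start: Tuple[int, int] = (8, 8)
    displacement: Tuple[int, int] = (2, 0)
    # focus_stack
    blur_step: float = 0.6
    # noise_pair
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.frames < 1:
            raise ValueError("need at least one frame")
        hi = 2**self.bit_depth - 1
        if not (0 <= self.background <= hi and 0 <= self.foreground <= hi):
            raise ValueError("intensities out of range for the bit depth")


def square_position(spec: SyntheticSpec, t: int) -> Tuple[int, int]:
    """Top-left corner of the square in frame ``t`` (0-based)."""
    r = spec.start[0] + t * spec.displacement[0]
    c = spec.start[1] + t * spec.displacement[1]
    return r, c


def focal_index(spec: SyntheticSpec) -> int:
    """Ground-truth focal frame of a focus stack (0-based, central frame)."""
    return (spec.frames - 1) // 2


def _moving_square(spec: SyntheticSpec) -> tuple:
    frames = []
    for t in range(spec.frames):
        r, c = square_position(spec, t)
        if r < 0 or c < 0 or r + spec.square_size > spec.shape[0] or c + spec.square_size > spec.shape[1]:
            raise ValueError(f"square leaves the frame at step {t}")
        img = np.full(spec.shape, spec.background, dtype=np.int64)
        img[r : r + spec.square_size, c : c + spec.square_size] = spec.foreground
        frames.append(img)
    return tuple(frames)


def _focus_stack(spec: SyntheticSpec) -> tuple:
    base = np.full(spec.shape, float(spec.background))
    r0, c0 = spec.start
    s = spec.square_size
    base[r0 : r0 + s, c0 : c0 + s] = spec.foreground
    # a second, offset structure so defocus mixes several edges
    r1 = min(spec.shape[0] - s // 2, r0 + 2 * s)
    c1 = min(spec.shape[1] - s // 2, c0 + 2 * s)
    base[r1 : r1 + s // 2, c1 : c1 + s // 2] = spec.foreground // 2
    center = focal_index(spec)
    hi = 2**spec.bit_depth - 1
    frames = []
    for t in range(spec.frames):
        # sqrt schedule: consecutive frames differ by a constant blur in
        # quadrature, so the largest image change happens at the focal pair
        # where fine detail is still present
        sigma = spec.blur_step * abs(t - center) ** 0.5
        img = gaussian_filter(base, sigma=sigma, mode="nearest") if sigma > 0 else base
        frames.append(np.clip(np.round(img), 0, hi).astype(np.int64))
    return tuple(frames)


def _noise_pair(spec: SyntheticSpec) -> tuple:
    rng = np.random.default_rng(spec.seed)
    hi = 2**spec.bit_depth - 1
    a = rng.integers(0, hi + 1, size=spec.shape)
    b = a.copy()
    flip = rng.random(spec.shape) < spec.noise_rate
    b[flip] = rng.integers(0, hi + 1, size=int(flip.sum()))
    return (a.astype(np.int64), b.astype(np.int64))


def synth_sequence(spec: SyntheticSpec) -> FrameSequence:
    """Generate the sequence described by ``spec`` (deterministic per seed)."""
    if spec.kind == "moving_square":
        frames = _moving_square(spec)
    elif spec.kind == "focus_stack":
        frames = _focus_stack(spec)
    else:
        frames = _noise_pair(spec)
    return FrameSequence(frames=frames, bit_depth=spec.bit_depth)
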