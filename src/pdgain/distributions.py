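"""Discretised reference distributions for histogram-level studies.

Each family maps an integer support to counts ``round(10**c * f(x))`` where
``f`` is the continuous density and ``round`` is half-away-from-zero (Matlab
semantics).  Zero counts produced by rounding the tails are retained: they
are legitimate empty target bins for an exchange.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .histogram import CountHistogram

__all__ = ["DistributionSpec", "generate_histogram", "FAMILIES"]

FAMILIES = ("levy", "cauchy", "gauss", "rayleigh")

# (family, c, sigma, b) -> default integer support [x_min, x_max]
_PRINTED_SUPPORTS = {
    ("levy", 5, None, None): (1, 256),
    ("levy", 7, None, None): (1, 256),
    ("levy", 3, None, None): (1, 85),
    ("cauchy", 7, None, None): (-127, 127),
    ("cauchy", 3.5, None, None): (-44, 44),
    ("gauss", 4, 1, None): (-4, 4),
    ("gauss", 3, 10, None): (-29, 29),
    ("gauss", 4, 10, None): (-36, 36),
    ("gauss", 10, 10, None): (-64, 64),
    ("rayleigh", 10, None, 16): (1, 108),
}


def _key(family: str, c: float, sigma, b) -> tuple:
    def norm(v):
        if v is None:
            return None
        return int(v) if float(v) == int(v) else float(v)

    return (family, norm(c), norm(sigma), norm(b))


@dataclass(frozen=True)
class DistributionSpec:
    """Parameter set for one discretised density.

    ``support`` defaults to the canonical interval for the printed
    family/parameter combinations; other combinations are allowed but must
    state a support explicitly and trigger a warning unless
    ``allow_nonstandard`` is set.
    """

    family: str
    c: float
    sigma: float | None = None
    b: float | None = None
    support: Tuple[int, int] | None = None
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "gauss" and self.sigma is None:
            raise ValueError("gauss requires sigma")
        if self.family == "rayleigh" and self.b is None:
            raise ValueError("rayleigh requires b")
        key = _key(self.family, self.c, self.sigma, self.b)
        default = _PRINTED_SUPPORTS.get(key)
        support = self.support
        if support is None:
            if default is None:
                raise ValueError(
                    "non-standard parameter combination requires an explicit support"
                )
            support = default
        elif default is None or tuple(support) != default:
            if not self.allow_nonstandard:
                warnings.warn(
                    "parameter/support combination differs from the canonical "
                    "set; pass allow_nonstandard=True to silence",
                    stacklevel=2,
                )
        lo, hi = int(support[0]), int(support[1])
        if hi < lo:
            raise ValueError("empty support")
        object.__setattr__(self, "support", (lo, hi))


def _density(family: str, x: np.ndarray, sigma, b) -> np.ndarray:
    x = x.astype(np.float64)
    if family == "levy":
        # unit-scale Levy: exp(-1/(2x)) / (sqrt(2*pi) * x**1.5), x > 0
        return np.exp(-1.0 / (2.0 * x)) / (math.sqrt(2.0 * math.pi) * x**1.5)
    if family == "cauchy":
        return 1.0 / (math.pi * (1.0 + x**2))
    if family == "gauss":
        return np.exp(-(x**2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2.0 * math.pi))
    if family == "rayleigh":
        return (x / b**2) * np.exp(-(x**2) / (2.0 * b**2))
    raise ValueError(f"unknown family {family!r}")  # pragma: no cover


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def generate_histogram(spec: DistributionSpec) -> CountHistogram:
    """Histogram with count ``round(10**c * f(x))`` at each integer ``x``.

    Deterministic: identical specs produce identical histograms.
    """
    lo, hi = spec.support
    x = np.arange(lo, hi + 1)
    if spec.family in ("levy", "rayleigh") and lo < 1:
        raise ValueError(f"{spec.family} support must start at x >= 1")
    f = _density(spec.family, x, spec.sigma, spec.b)
    counts = _round_half_away(10.0 ** float(spec.c) * f).astype(np.int64)
    return CountHistogram(labels=x, counts=counts)
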