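"""Frame-pair transforms: per-pixel gain maps and macroscopic spectra.

Given two same-shape frames ``a`` and ``b``, each pixel position realises one
exchange ``a_i -> b_i`` against the basis histogram (by default the first
frame's whole-image histogram, so the removed intensity always has
``n_l >= 1``).  Two macroscopic summaries are derived:

* PDGE  ``I_alpha = sum_i |Omega(a_i -> b_i)| = sum_lm n_lm |Omega(l -> m)]``
  — every pixel contributes, weighted by transition multiplicity.
* PDGED ``P_alpha = sum_lm chi_lm |Omega(l -> m)|`` with ``chi_lm = 1`` iff
  the transition ``(l, m)`` is realised at least once — each distinct
  intensity pair counts exactly once, which emphasises rare transitions.

Both sums are accumulated with exact (fsum) summation so the two forms of
``I_alpha`` — per-pixel and per-transition — coincide bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import pdg_counts
from .histogram import AlphaGrid, CountHistogram

__all__ = [
    "FrameSequence",
    "TransitionTable",
    "PDGMap",
    "SpectrumTable",
    "transition_table",
    "pdg_map",
    "pdge",
    "pdged",
    "spectra",
    "classify_spectrum",
]


@dataclass(frozen=True)
class FrameSequence:
    """Ordered stack of same-shape integer grayscale frames."""

    frames: tuple
    bit_depth: int

    def __post_init__(self) -> None:
        frames = tuple(np.asarray(f) for f in self.frames)
        if not frames:
            raise ValueError("a sequence needs at least one frame")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        shape = frames[0].shape
        hi = 2**self.bit_depth - 1
        for i, f in enumerate(frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not two-dimensional")
            if f.shape != shape:
                raise ValueError(f"frame {i} shape {f.shape} != {shape}")
            if not np.issubdtype(f.dtype, np.integer):
                raise ValueError(f"frame {i} is not an integer raster")
            if f.min() < 0 or f.max() > hi:
                raise ValueError(
                    f"frame {i} intensities outside [0, {hi}] for {self.bit_depth}-bit"
                )
        object.__setattr__(self, "frames", frames)

    @property
    def shape(self) -> tuple:
        return self.frames[0].shape

    @property
    def n_levels(self) -> int:
        return 2**self.bit_depth

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class TransitionTable:
    """Counts ``n_lm`` of realised positionwise transitions ``l -> m``."""

    sources: np.ndarray  # l per realised pair
    targets: np.ndarray  # m per realised pair
    counts: np.ndarray  # n_lm per realised pair
    total: int  # number of pixels

    def as_dict(self) -> dict:
        return {
            (int(l), int(m)): int(c)
            for l, m, c in zip(self.sources, self.targets, self.counts)
        }

    def source_histogram(self, n_levels: int) -> CountHistogram:
        """Marginal over targets: the first frame's intensity histogram."""
        counts = np.zeros(n_levels, dtype=np.int64)
        np.add.at(counts, self.sources, self.counts)
        return CountHistogram(np.arange(n_levels), counts)

    def target_histogram(self, n_levels: int) -> CountHistogram:
        counts = np.zeros(n_levels, dtype=np.int64)
        np.add.at(counts, self.targets, self.counts)
        return CountHistogram(np.arange(n_levels), counts)


def transition_table(frame_a: np.ndarray, frame_b: np.ndarray) -> TransitionTable:
    """Exact tally of positionwise intensity pairs between two frames."""
    a = np.asarray(frame_a)
    b = np.asarray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    a = a.ravel().astype(np.int64)
    b = b.ravel().astype(np.int64)
    width = int(max(a.max(), b.max())) + 1
    combined = a * width + b
    uniq, counts = np.unique(combined, return_counts=True)
    return TransitionTable(
        sources=uniq // width,
        targets=uniq % width,
        counts=counts.astype(np.int64),
        total=a.size,
    )


@dataclass(frozen=True)
class PDGMap:
    """Per-pixel Omega raster for one frame pair and one alpha."""

    alpha: float
    log_base: float
    values: np.ndarray
    basis: str = "first"


def _basis_histogram(
    frame_a: np.ndarray, frame_b: np.ndarray, basis: str, n_levels: int | None = None
) -> CountHistogram:
    if n_levels is None:
        n_levels = int(max(frame_a.max(), frame_b.max())) + 1
    if basis == "first":
        counts = np.bincount(np.asarray(frame_a).ravel(), minlength=n_levels)
    elif basis == "pooled":
        counts = np.bincount(
            np.concatenate([np.asarray(frame_a).ravel(), np.asarray(frame_b).ravel()]),
            minlength=n_levels,
        )
    else:
        raise ValueError("basis must be 'first' or 'pooled'")
    return CountHistogram(np.arange(len(counts)), counts)


def _counts_for(hist: CountHistogram, labels: np.ndarray) -> np.ndarray:
    """Counts of ``labels`` in ``hist`` (vectorised label lookup)."""
    order = np.argsort(hist.labels, kind="stable")
    sorted_labels = hist.labels[order]
    pos = np.searchsorted(sorted_labels, labels)
    if np.any(pos >= len(sorted_labels)) or np.any(sorted_labels[pos] != labels):
        raise KeyError("transition label absent from the basis histogram")
    return hist.counts[order[pos]]


def _pair_omegas(
    table: TransitionTable,
    base_hist: CountHistogram,
    alpha: float,
    log_base: float,
) -> np.ndarray:
    nl = _counts_for(base_hist, table.sources)
    nm = _counts_for(base_hist, table.targets)
    return pdg_counts(
        nl,
        nm,
        alpha=alpha,
        c_alpha=base_hist.c_alpha(alpha),
        k_occupied=base_hist.k_occupied,
        n=base_hist.n,
        log_base=log_base,
        same_bin=table.sources == table.targets,
    )


def pdg_map(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    alpha: float,
    log_base: float = 2.0,
    basis: str = "first",
    cache: bool = True,
) -> PDGMap:
    """Per-pixel Omega(a_i -> b_i) raster against the basis histogram.

    With ``cache=True`` each distinct transition ``(a_i, b_i)`` is evaluated
    once and broadcast to all pixels realising it; the uncached path computes
    every pixel independently and produces a bit-identical raster.
    """
    a = np.asarray(frame_a)
    b = np.asarray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    hist = _basis_histogram(a, b, basis)
    counts = hist.counts  # labels are 0..L-1, direct indexing
    if cache:
        width = len(counts)
        combined = a.ravel().astype(np.int64) * width + b.ravel().astype(np.int64)
        uniq, inverse = np.unique(combined, return_inverse=True)
        ls, ms = uniq // width, uniq % width
        omega_uniq = pdg_counts(
            counts[ls],
            counts[ms],
            alpha=alpha,
            c_alpha=hist.c_alpha(alpha),
            k_occupied=hist.k_occupied,
            n=hist.n,
            log_base=log_base,
            same_bin=ls == ms,
        )
        values = omega_uniq[inverse].reshape(a.shape)
    else:
        values = pdg_counts(
            counts[a.ravel()],
            counts[b.ravel()],
            alpha=alpha,
            c_alpha=hist.c_alpha(alpha),
            k_occupied=hist.k_occupied,
            n=hist.n,
            log_base=log_base,
            same_bin=(a.ravel() == b.ravel()),
        ).reshape(a.shape)
    return PDGMap(alpha=float(alpha), log_base=float(log_base), values=values, basis=basis)


def pdge(
    table: TransitionTable,
    base_hist: CountHistogram,
    alpha: float,
    log_base: float = 2.0,
) -> float:
    """PDGE ``I_alpha``: multiplicity-weighted sum of |Omega| over transitions.

    Summation is exact, so the result equals the per-pixel ``sum_i |Omega|``
    over the corresponding gain map bit for bit.
    """
    omegas = _pair_omegas(table, base_hist, alpha, log_base)
    contributions = np.repeat(np.abs(omegas), table.counts)
    return float(math.fsum(contributions))


def pdged(
    table: TransitionTable,
    base_hist: CountHistogram,
    alpha: float,
    log_base: float = 2.0,
) -> float:
    """PDGED ``P_alpha``: each realised intensity pair counted exactly once.

    Deduplication is by the pair ``(l, m)``, not by numeric Omega value:
    distinct pairs contribute separately even when their gains coincide.
    """
    omegas = _pair_omegas(table, base_hist, alpha, log_base)
    return float(math.fsum(np.abs(omegas)))


@dataclass(frozen=True)
class SpectrumTable:
    """Long-form I/P spectra: one row per (frame pair, alpha)."""

    data: pd.DataFrame = field(compare=False)
    alphas: tuple = ()
    lag: int = 1
    log_base: float = 2.0

    COLUMNS = ("pair_index", "alpha", "I_alpha", "P_alpha")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"spectrum table missing columns {sorted(missing)}")

    def to_csv(self, path_or_buf, comment: str | None = None) -> None:
        header = f"# pdgain spectra; alphas={list(self.alphas)}; lag={self.lag}; log_base={self.log_base}\n"
        if comment:
            header += f"# {comment}\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header)
            self.data.to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header)
                self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, lag: int = 1, log_base: float = 2.0) -> "SpectrumTable":
        df = pd.read_csv(path_or_buf, comment="#")
        alphas = tuple(sorted(df["alpha"].unique()))
        return cls(data=df, alphas=alphas, lag=lag, log_base=log_base)

    def pair(self, t: int) -> pd.DataFrame:
        return self.data[self.data["pair_index"] == t]


def spectra(
    seq: FrameSequence,
    grid: AlphaGrid | Sequence[float],
    lag: int = 1,
    basis: str = "first",
) -> SpectrumTable:
    """I/P spectra for every frame pair ``(t, t + lag)`` and every alpha.

    Pair ``t`` (1-based) uses frame ``t`` as basis histogram; a sequence of N
    frames yields ``(N - lag) * len(grid)`` rows.
    """
    if not isinstance(grid, AlphaGrid):
        grid = AlphaGrid(tuple(grid))
    lag = int(lag)
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if len(seq) <= lag:
        raise ValueError(f"sequence of {len(seq)} frames is too short for lag {lag}")
    rows = []
    for t in range(len(seq) - lag):
        a, b = seq[t], seq[t + lag]
        table = transition_table(a, b)
        hist = _basis_histogram(a, b, basis, n_levels=seq.n_levels)
        for alpha in grid:
            omegas = _pair_omegas(table, hist, alpha, grid.log_base)
            i_alpha = float(math.fsum(np.repeat(np.abs(omegas), table.counts)))
            p_alpha = float(math.fsum(np.abs(omegas)))
            rows.append((t + 1, alpha, i_alpha, p_alpha))
    df = pd.DataFrame(rows, columns=list(SpectrumTable.COLUMNS))
    return SpectrumTable(
        data=df, alphas=tuple(grid.values), lag=lag, log_base=grid.log_base
    )


def classify_spectrum(
    alphas: Iterable[float], values: Iterable[float]
) -> tuple[bool, float]:
    """Peak-vs-monotone readout of a spectrum ``f(alpha)``.

    Returns ``(has_peak, argmax_alpha)``: ``has_peak`` is true when the
    maximum is attained strictly inside the grid (a multifractality
    indicator); a maximum at either end of a monotone-looking spectrum reads
    as unifractal/Euclidean content.
    """
    alphas = np.asarray(list(alphas), dtype=float)
    values = np.asarray(list(values), dtype=float)
    if alphas.shape != values.shape or alphas.size < 3:
        raise ValueError("need matching alpha/value arrays of length >= 3")
    idx = int(np.argmax(values))
    has_peak = 0 < idx < len(values) - 1
    return has_peak, float(alphas[idx])
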