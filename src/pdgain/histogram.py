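"""Count histograms and alpha grids.

A :class:`CountHistogram` stores integer occurrence counts ``n_j`` over a set
of labelled bins.  All entropic quantities in :mod:`pdgain.core` operate on
this type; the probability vector ``p_j = n_j / n`` is never materialised
unless needed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = ["CountHistogram", "AlphaGrid", "DEFAULT13", "GRID40"]

LabelLike = Union[int, np.integer]


@dataclass(frozen=True)
class CountHistogram:
    """Integer occurrence counts over labelled bins.

    Parameters
    ----------
    labels:
        Stable integer identifiers for the bins (e.g. intensity values).
    counts:
        Non-negative occurrence counts, one per label.  Zero-count bins are
        legal and retained: they are valid targets of an exchange.
    """

    labels: np.ndarray
    counts: np.ndarray
    _index: dict = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        counts = np.asarray(self.counts)
        if labels.ndim != 1 or counts.ndim != 1:
            raise ValueError("labels and counts must be one-dimensional")
        if labels.shape != counts.shape:
            raise ValueError("labels and counts must have the same length")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(np.unique(labels)) != len(labels):
            raise ValueError("duplicate bin labels")
        object.__setattr__(self, "labels", labels.astype(np.int64))
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(
            self, "_index", {int(lab): i for i, lab in enumerate(labels)}
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_counts(
        cls, counts: Sequence[int], labels: Sequence[int] | None = None
    ) -> "CountHistogram":
        """Build from a plain count vector; labels default to ``1..k``."""
        counts = np.asarray(counts)
        if labels is None:
            labels = np.arange(1, len(counts) + 1)
        return cls(np.asarray(labels), counts)

    @classmethod
    def from_values(
        cls, values: Iterable[int], n_levels: int | None = None
    ) -> "CountHistogram":
        """Tally raw integer observations (e.g. pixel intensities).

        With ``n_levels`` given, bins ``0..n_levels-1`` are all present (zero
        counts retained); otherwise only the observed range is covered.
        """
        values = np.asarray(values).ravel()
        if values.size == 0:
            raise ValueError("empty distribution")
        if np.any(values < 0):
            raise ValueError("negative values; use explicit labels instead")
        length = int(values.max()) + 1 if n_levels is None else int(n_levels)
        counts = np.bincount(values, minlength=length)
        return cls(np.arange(length), counts)

    # -- basic accessors ---------------------------------------------------

    @property
    def k(self) -> int:
        """Number of bins (occupied or not)."""
        return len(self.counts)

    @property
    def n(self) -> int:
        """Total number of observations."""
        return int(self.counts.sum())

    @property
    def k_occupied(self) -> int:
        """Number of bins with at least one observation."""
        return int(np.count_nonzero(self.counts))

    def index_of(self, label: LabelLike) -> int:
        try:
            return self._index[int(label)]
        except KeyError:
            raise KeyError(f"no bin labelled {label!r}") from None

    def count_of(self, label: LabelLike) -> int:
        return int(self.counts[self.index_of(label)])

    def probabilities(self) -> np.ndarray:
        n = self.n
        if n == 0:
            raise ValueError("empty distribution")
        return self.counts / n

    def c_alpha(self, alpha: float):
        """Normalisation constant ``C_alpha = sum_j n_j**alpha`` (occupied bins).

        Returns an exact Python int for integer alpha (counts can be large
        enough that ``n_j**4`` overflows int64), a float otherwise.
        """
        occ = self.counts[self.counts > 0]
        if float(alpha) == int(alpha):
            return sum(int(c) ** int(alpha) for c in occ)
        return float(np.sum(occ.astype(np.float64) ** float(alpha)))

    # -- derived histograms ------------------------------------------------

    def remove_one(self, label: LabelLike) -> "CountHistogram":
        """Histogram with one occurrence of ``label`` removed."""
        i = self.index_of(label)
        if self.counts[i] < 1:
            raise ValueError("phenomenon absent")
        counts = self.counts.copy()
        counts[i] -= 1
        return CountHistogram(self.labels, counts)

    def exchange(self, l: LabelLike, m: LabelLike) -> "CountHistogram":
        """Histogram after the exchange ``l -> m`` (remove one l, add one m)."""
        il, im = self.index_of(l), self.index_of(m)
        if self.counts[il] < 1:
            raise ValueError("cannot remove from empty bin")
        counts = self.counts.copy()
        counts[il] -= 1
        counts[im] += 1
        return CountHistogram(self.labels, counts)

    # -- serialization -----------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        """Write a two-column CSV ``bin_label,count``."""
        out = io.StringIO()
        out.write("bin_label,count\n")
        for lab, cnt in zip(self.labels, self.counts):
            out.write(f"{int(lab)},{int(cnt)}\n")
        data = out.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(data)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(data)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CountHistogram":
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf) as fh:
                lines = fh.read().splitlines()
        labels, counts = [], []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("bin_label"):
                continue
            lab, cnt = line.split(",")
            labels.append(int(lab))
            counts.append(int(cnt))
        return cls(np.asarray(labels), np.asarray(counts))


#: The 13-point alpha grid used throughout spectrum clustering.
DEFAULT13 = (0.1, 0.3, 0.5, 0.7, 0.99, 1.3, 1.5, 1.7, 2.0, 2.5, 3.0, 3.5, 4.0)

#: The finer 40-point grid {0.1..0.9, 0.99, 1.1..4.0} for spectrum inspection.
GRID40 = tuple(
    [round(0.1 * i, 10) for i in range(1, 10)]
    + [0.99]
    + [round(0.1 * i, 10) for i in range(11, 41)]
)


@dataclass(frozen=True)
class AlphaGrid:
    """Strictly increasing grid of non-negative alpha values."""

    values: tuple
    log_base: float = 2.0

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if any(v < 0 for v in vals):
            raise ValueError("alpha values must be non-negative")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("alpha values must be strictly increasing")
        if self.log_base not in (2.0, 2, np.e):
            raise ValueError("log_base must be 2 or e")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "log_base", float(self.log_base))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @classmethod
    def named(cls, name: str, log_base: float = 2.0) -> "AlphaGrid":
        """Look up a named grid: ``default13`` or ``grid40``."""
        grids = {"default13": DEFAULT13, "grid40": GRID40}
        try:
            return cls(grids[name], log_base=log_base)
        except KeyError:
            raise ValueError(
                f"unknown grid {name!r}; expected one of {sorted(grids)}"
            ) from None

    @classmethod
    def parse(cls, text: str, log_base: float = 2.0) -> "AlphaGrid":
        """Parse a named grid or a comma-separated list of alpha values."""
        text = text.strip()
        if text in ("default13", "grid40"):
            return cls.named(text, log_base=log_base)
        return cls(tuple(float(t) for t in text.split(",")), log_base=log_base)
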