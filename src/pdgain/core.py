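"""Renyi entropy, point information gain, and point divergence gain.

The central quantity is the point divergence gain

    Omega_alpha(l -> m) = H_alpha(P^(l->m)) - H_alpha(P),

the change in Renyi entropy when one occurrence of phenomenon ``l`` is
removed from the count histogram ``P`` and one occurrence of ``m`` is added.
For generic alpha this reduces to the closed form

    Omega = 1/(1-alpha) * log( 1 + [ (n_l-1)^a - n_l^a + (n_m+1)^a - n_m^a ] / C_a )

with ``C_a = sum_j n_j^a``.  Special branches:

* ``alpha = 1``: Shannon limit, evaluated as an exact entropy difference
  (only the two touched bins contribute; the ``0*log 0 = 0`` convention
  covers removal from a singleton bin).
* ``alpha = 2``: collision entropy, ``Omega_2 = -log(2/C_2*(n_m-n_l+1) + 1)``.
* ``alpha = 0``: support-size semantics, ``H_0 = log(#occupied bins)``; the
  exchange only moves the value when it changes the support (``n_l = 1``
  empties a bin, ``n_m = 0`` fills one).

Sign convention: removing a rare point and supplying a frequent one
(``n_l << n_m``) gives a negative gain, and vice versa.  The value is exactly
zero when ``l = m`` or when ``n_l = n_m + 1`` (the exchange permutes the count
multiset).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .histogram import CountHistogram

__all__ = [
    "renyi_entropy",
    "pig",
    "pdg",
    "pdg_alpha2",
    "pdg_counts",
    "pdg_matrix",
    "PDGMatrix",
]


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not math.isfinite(alpha) or alpha < 0:
        raise ValueError("alpha must be a non-negative real number")
    return alpha


def _ln_base(log_base: float) -> float:
    if log_base in (2, 2.0):
        return math.log(2.0)
    if log_base == math.e:
        return 1.0
    raise ValueError("log_base must be 2 or e")


def renyi_entropy(hist: CountHistogram, alpha: float, log_base: float = 2.0) -> float:
    """Renyi entropy ``H_alpha`` of a count histogram, in bits (or nats).

    ``alpha = 1`` returns the Shannon entropy; ``alpha = 0`` the log of the
    number of occupied bins.  Empty bins never contribute (``0^alpha`` terms
    are excluded for every alpha, including ``alpha = 0``).
    """
    alpha = _check_alpha(alpha)
    ln_b = _ln_base(log_base)
    n = hist.n
    if n == 0:
        raise ValueError("empty distribution")
    occ = hist.counts[hist.counts > 0].astype(np.float64)
    if alpha == 0.0:
        return math.log(len(occ)) / ln_b
    p = occ / n
    if alpha == 1.0:
        return -math.fsum(pi * math.log(pi) for pi in p) / ln_b
    s = math.fsum(pi**alpha for pi in p)
    return math.log(s) / ((1.0 - alpha) * ln_b)


def pig(hist: CountHistogram, i, alpha: float, log_base: float = 2.0) -> float:
    """Point information gain: entropy change after removing one ``i``.

    ``Gamma_alpha(i) = H_alpha(P^(i)) - H_alpha(P)`` where ``P^(i)`` omits one
    occurrence of phenomenon ``i`` (total drops to ``n - 1``).
    """
    alpha = _check_alpha(alpha)
    if hist.count_of(i) < 1:
        raise ValueError("phenomenon absent")
    if hist.n < 2:
        raise ValueError("resulting distribution empty")
    reduced = hist.remove_one(i)
    return renyi_entropy(reduced, alpha, log_base) - renyi_entropy(
        hist, alpha, log_base
    )


# ---------------------------------------------------------------------------
# point divergence gain
# ---------------------------------------------------------------------------


def _pdg_scalar_counts(
    nl: int, nm: int, alpha: float, c_alpha: float, k_occ: int, ln_b: float
) -> float:
    """Omega for one (n_l, n_m) pair of a histogram with constant C_alpha.

    Uses exact integer powers when alpha is a small integer; the log argument
    is always evaluated in log1p style because delta/C is often tiny.
    """
    if nl < 1:
        raise ValueError("cannot remove from empty bin")
    if alpha == 0.0:
        k_after = k_occ - (1 if nl == 1 else 0) + (1 if nm == 0 else 0)
        if ln_b == math.log(2.0):
            return math.log2(k_after / k_occ)
        return math.log(k_after / k_occ)
    if alpha == int(alpha) and alpha <= 64:
        # exact big-int numerator; int/int division rounds once
        a = int(alpha)
        delta_int = (nl - 1) ** a - nl**a + (nm + 1) ** a - nm**a
        ratio = delta_int / int(c_alpha)
    else:
        delta = ((nl - 1) ** alpha - nl**alpha) + ((nm + 1) ** alpha - nm**alpha)
        ratio = delta / c_alpha
    return math.log1p(ratio) / ((1.0 - alpha) * ln_b)


def _pdg_shannon(nl: int, nm: int, n: int, ln_b: float) -> float:
    """Exact Shannon-limit Omega_1; valid for n_l >= 1, n_m >= 0."""

    def xlx(c: int) -> float:
        return c * math.log(c) if c > 0 else 0.0

    return ((xlx(nl) - xlx(nm + 1)) + (xlx(nm) - xlx(nl - 1))) / (n * ln_b)


def pdg(hist: CountHistogram, l, m, alpha: float, log_base: float = 2.0) -> float:
    """Point divergence gain ``Omega_alpha(l -> m)`` for one exchange.

    Exactly zero when ``l = m`` or ``n_l = n_m + 1``; negative when the
    removed phenomenon is much rarer than the supplied one; positive in the
    opposite case.
    """
    alpha = _check_alpha(alpha)
    ln_b = _ln_base(log_base)
    nl = hist.count_of(l)
    nm = hist.count_of(m)
    if nl < 1:
        raise ValueError("cannot remove from empty bin")
    if hist.index_of(l) == hist.index_of(m):
        return 0.0
    if alpha == 1.0:
        return _pdg_shannon(nl, nm, hist.n, ln_b)
    c_alpha = hist.c_alpha(alpha)
    return _pdg_scalar_counts(nl, nm, alpha, c_alpha, hist.k_occupied, ln_b)


def pdg_alpha2(hist: CountHistogram, l, m, log_base: float = 2.0) -> float:
    """Collision-entropy special case ``Omega_2 = -log(2/C_2*(n_m-n_l+1)+1)``.

    Agrees with ``pdg(..., alpha=2)`` to floating-point tolerance; given
    ``C_2`` it depends on the counts only through ``n_m - n_l``.
    """
    ln_b = _ln_base(log_base)
    nl = hist.count_of(l)
    nm = hist.count_of(m)
    if nl < 1:
        raise ValueError("cannot remove from empty bin")
    if hist.index_of(l) == hist.index_of(m):
        return 0.0
    c2 = int(hist.c_alpha(2.0))
    return -math.log1p(2.0 * (nm - nl + 1) / c2) / ln_b


def pdg_counts(
    nl,
    nm,
    alpha: float,
    c_alpha: float,
    k_occupied: int,
    n: int,
    log_base: float = 2.0,
    same_bin=None,
) -> np.ndarray:
    """Vectorised Omega over arrays of source/target counts.

    All entries share one basis histogram, summarised by ``c_alpha``,
    ``k_occupied`` and ``n``.  ``same_bin`` marks entries where source and
    target are the same bin (always zero).  Entries with ``n_l = 0`` are
    undefined and returned as NaN.
    """
    alpha = _check_alpha(alpha)
    ln_b = _ln_base(log_base)
    nl = np.asarray(nl, dtype=np.float64)
    nm = np.asarray(nm, dtype=np.float64)
    nl, nm = np.broadcast_arrays(nl, nm)
    if same_bin is None:
        same_bin = np.zeros(nl.shape, dtype=bool)
    same_bin = np.broadcast_to(np.asarray(same_bin, dtype=bool), nl.shape)

    out = np.full(nl.shape, np.nan)
    valid = nl >= 1
    active = valid & ~same_bin

    if alpha == 0.0:
        k_after = k_occupied - (nl == 1).astype(np.int64) + (nm == 0).astype(np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = k_after / k_occupied
            vals = np.log2(ratio) if ln_b == math.log(2.0) else np.log(ratio)
    elif alpha == 1.0:
        # terms paired so the n_l = n_m + 1 locus cancels exactly in floats
        vals = (
            (xlogy(nl, nl) - xlogy(nm + 1, nm + 1))
            + (xlogy(nm, nm) - xlogy(nl - 1, nl - 1))
        ) / (n * ln_b)
    else:
        with np.errstate(invalid="ignore"):
            delta = ((nl - 1) ** alpha - nl**alpha) + ((nm + 1) ** alpha - nm**alpha)
        vals = np.log1p(delta / c_alpha) / ((1.0 - alpha) * ln_b)

    out[active] = vals[active]
    out[valid & same_bin] = 0.0
    return out


@dataclass(frozen=True)
class PDGMatrix:
    """k x k table of Omega_alpha(l -> m) for one basis histogram.

    Entry ``(l, m)`` (row = source bin, column = target bin) holds the gain of
    the exchange ``l -> m``.  Rows of empty bins are NaN (undefined: nothing
    to remove).
    """

    alpha: float
    log_base: float
    c_alpha: float
    labels: np.ndarray
    values: np.ndarray

    @property
    def k(self) -> int:
        return len(self.labels)

    def value(self, l, m) -> float:
        idx = {int(lab): i for i, lab in enumerate(self.labels)}
        return float(self.values[idx[int(l)], idx[int(m)]])

    def to_csv(self, path_or_buf) -> None:
        """k x k CSV; first row/column carry the bin labels."""
        out = io.StringIO()
        out.write("l\\m," + ",".join(str(int(x)) for x in self.labels) + "\n")
        for lab, row in zip(self.labels, self.values):
            out.write(str(int(lab)) + "," + ",".join(repr(float(v)) for v in row) + "\n")
        data = out.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(data)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(data)

    def to_npz(self, path) -> None:
        """Binary container with metadata {alpha, log_base, c_alpha}."""
        np.savez(
            path,
            values=self.values,
            labels=self.labels,
            alpha=self.alpha,
            log_base=self.log_base,
            c_alpha=self.c_alpha,
        )

    @classmethod
    def from_npz(cls, path) -> "PDGMatrix":
        with np.load(path) as data:
            return cls(
                alpha=float(data["alpha"]),
                log_base=float(data["log_base"]),
                c_alpha=float(data["c_alpha"]),
                labels=data["labels"],
                values=data["values"],
            )


def pdg_matrix(
    hist: CountHistogram, alpha: float, log_base: float = 2.0
) -> PDGMatrix:
    """Full Omega table over all bin pairs of a histogram.

    ``C_alpha`` is computed once and shared by all cells.
    """
    alpha = _check_alpha(alpha)
    counts = hist.counts
    c_alpha = hist.c_alpha(alpha) if alpha not in (0.0, 1.0) else 0.0
    nl = counts[:, None]
    nm = counts[None, :]
    same = np.eye(hist.k, dtype=bool)
    values = pdg_counts(
        nl,
        nm,
        alpha=alpha,
        c_alpha=c_alpha,
        k_occupied=hist.k_occupied,
        n=hist.n,
        log_base=log_base,
        same_bin=same,
    )
    return PDGMatrix(
        alpha=alpha,
        log_base=float(2.0 if log_base in (2, 2.0) else math.e),
        c_alpha=float(c_alpha),
        labels=hist.labels.copy(),
        values=values,
    )
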