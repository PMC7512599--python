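"""Independent brute-force oracles used to check the closed-form code paths.

Everything here works from explicit probability vectors and plain entropy
definitions; nothing reuses the package's closed forms.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def oracle_entropy(counts, alpha, base: float = 2.0) -> float:
    """H_alpha from an explicit probability vector (occupied bins only)."""
    counts = [int(c) for c in counts]
    n = sum(counts)
    assert n >= 1
    probs = [c / n for c in counts if c > 0]
    ln_b = math.log(base)
    if alpha == 0:
        return math.log(len(probs)) / ln_b
    if alpha == 1:
        return -math.fsum(p * math.log(p) for p in probs) / ln_b
    s = math.fsum(p**alpha for p in probs)
    return math.log(s) / ((1.0 - alpha) * ln_b)


def exchange_counts(counts, l_idx: int, m_idx: int):
    out = list(counts)
    assert out[l_idx] >= 1
    out[l_idx] -= 1
    out[m_idx] += 1
    return out


def oracle_pdg(counts, l_idx, m_idx, alpha, base: float = 2.0) -> float:
    """Direct H(P^(l->m)) - H(P) from explicit probability vectors."""
    after = exchange_counts(counts, l_idx, m_idx)
    return oracle_entropy(after, alpha, base) - oracle_entropy(counts, alpha, base)


def oracle_pig(counts, i_idx, alpha, base: float = 2.0) -> float:
    out = list(counts)
    assert out[i_idx] >= 1
    out[i_idx] -= 1
    return oracle_entropy(out, alpha, base) - oracle_entropy(counts, alpha, base)


def enumerate_histograms(max_k: int, max_count: int):
    """All count vectors with 1 <= k <= max_k, entries 0..max_count, n >= 1."""
    for k in range(1, max_k + 1):
        for counts in itertools.product(range(max_count + 1), repeat=k):
            if sum(counts) >= 1:
                yield counts


def enumerate_exchanges(max_k: int, max_count: int):
    """All (counts, l_idx, m_idx) with n_l >= 1 over the exhaustive set."""
    for counts in enumerate_histograms(max_k, max_count):
        for l_idx in range(len(counts)):
            if counts[l_idx] < 1:
                continue
            for m_idx in range(len(counts)):
                yield counts, l_idx, m_idx


def exhaustive_arrays(max_k: int, max_count: int):
    """The exhaustive exchange set as flat arrays for vectorised checks.

    Returns (counts_matrix, l_idx, m_idx, row) where ``row`` maps each
    exchange to its histogram row in ``counts_matrix``.
    """
    hists = [list(c) + [0] * (max_k - len(c)) + [len(c)] for c in enumerate_histograms(max_k, max_count)]
    padded = np.array([h[:-1] for h in hists], dtype=np.int64)
    ks = np.array([h[-1] for h in hists], dtype=np.int64)
    rows, ls, ms = [], [], []
    for r, (counts, k) in enumerate(zip(padded, ks)):
        for l_idx in range(k):
            if counts[l_idx] < 1:
                continue
            for m_idx in range(k):
                rows.append(r)
                ls.append(l_idx)
                ms.append(m_idx)
    return padded, ks, np.array(ls), np.array(ms), np.array(rows)


def vector_entropy(padded_counts: np.ndarray, ks: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise H_alpha (base 2) of padded count matrices.

    Padding columns beyond each row's k are zero and therefore never
    contribute (empty bins are excluded for every alpha).
    """
    counts = padded_counts.astype(np.float64)
    n = counts.sum(axis=1)
    occupied = counts > 0
    ln2 = math.log(2.0)
    if alpha == 0:
        return np.log(occupied.sum(axis=1)) / ln2
    p = np.where(occupied, counts / n[:, None], 0.0)
    if alpha == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(occupied, p * np.log(p), 0.0)
        return -terms.sum(axis=1) / ln2
    s = np.where(occupied, p**alpha, 0.0).sum(axis=1)
    return np.log(s) / ((1.0 - alpha) * ln2)
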