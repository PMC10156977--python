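"""Classic single-number sequence descriptors: SE, MSE, HE and FD.

These four estimators operate on the purine/pyrimidine 0/1 encoding (entropy
and Hurst) or directly on the base string (fractal dimension) and serve both
standalone and as the +4 extension of the 44-feature combined vector.

Conventions, fixed once:

* Shannon entropy (SE) and modified Shannon entropy (MSE) use log base 2.
* The Hurst exponent (HE) is the single-scale rescaled-range estimate solved
  at the full series length n: HE = log(R_n / S_n) / log(n / 2), with S_n
  the population (divisor n) standard deviation. No multi-window regression.
* The fractal dimension (FD) uses sigma(n), the average count of 1s over all
  contiguous n x n submatrices of the N x N indicator matrix — the exact
  expectation of sampling submatrices at random — and reports the literal
  value FD = -(1/N) * sum_{n=2..N} log(sigma(n)) / log(n), which is negative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .seqio import BinarySequence, NucleotideSequence

logger = logging.getLogger("genetexture")

MSEMode = Literal["window", "runs"]

#: Default truncation of the indicator matrix (memory is O(cap^2)).
DEFAULT_FD_CAP = 1000


def shannon_entropy(bin_seq: BinarySequence) -> float:
    """Binary Shannon entropy -sum p_i log2 p_i, in [0, 1] bits.

    0 * log 0 is taken as 0, so a constant sequence has entropy 0 and a
    balanced one has entropy 1.
    """
    se = 0.0
    for p in (bin_seq.p0, bin_seq.p1):
        if p > 0:
            se -= p * np.log2(p)
    return float(se)


def _runs(bits: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of identical bits, in order."""
    change = np.flatnonzero(np.diff(bits)) + 1
    return np.split(bits, change)


def modified_shannon_entropy(
    bin_seq: BinarySequence, mode: MSEMode = "window"
) -> float:
    """Word-based entropy -sum w_j log2 w_j of the binary sequence.

    The word inventory depends on ``mode``:

    * ``"window"`` (default): the word length is the longest run of identical
      bits; w_j are the empirical frequencies of the overlapping windows of
      that length.
    * ``"runs"``: the words are the maximal runs themselves; w_j are the
      frequencies of each distinct (symbol, run length) word among all runs.
    """
    bits = bin_seq.bits
    if mode == "window":
        ell = max(len(r) for r in _runs(bits))
        windows = np.lib.stride_tricks.sliding_window_view(bits, ell)
        _, counts = np.unique(windows, axis=0, return_counts=True)
    elif mode == "runs":
        words = Counter((int(r[0]), len(r)) for r in _runs(bits))
        counts = np.array(list(words.values()))
    else:
        raise ValueError(f"unknown MSE mode {mode!r}")
    w = counts / counts.sum()
    return float(-np.sum(w * np.log2(w)))


@dataclass(frozen=True)
class RSIntermediates:
    """Audit trail of the rescaled-range calculation."""

    m: float
    X_t: np.ndarray
    R_n: float
    S_n: float
    HE: float


def hurst_exponent(
    bin_seq: BinarySequence, return_intermediates: bool = False
) -> float | tuple[float, RSIntermediates]:
    """Single-scale rescaled-range Hurst exponent of the binary sequence.

    R_n is the range of the cumulative deviations from the mean, S_n the
    population standard deviation; HE = log(R_n/S_n) / log(n/2). Raises
    ``ValueError`` for a constant sequence (S_n = 0, the ratio is undefined)
    and for n < 3 (the denominator log(n/2) vanishes at n = 2).
    """
    bits = bin_seq.bits.astype(float)
    n = bits.size
    if n < 3:
        raise ValueError(f"Hurst exponent undefined for length {n} < 3")
    m = bits.mean()
    S_n = float(np.sqrt(np.mean((bits - m) ** 2)))
    if S_n == 0.0:
        raise ValueError("Hurst exponent undefined for a constant sequence (zero variance)")
    X_t = np.cumsum(bits - m)
    R_n = float(X_t.max() - X_t.min())
    he = float(np.log(R_n / S_n) / np.log(n / 2.0))
    if return_intermediates:
        return he, RSIntermediates(m=float(m), X_t=X_t, R_n=R_n, S_n=S_n, HE=he)
    return he


def indicator_matrix(seq: NucleotideSequence, cap: int = DEFAULT_FD_CAP) -> np.ndarray:
    """N x N binary matrix with cell (i, j) = 1 iff base_i == base_j.

    N = min(sequence length, cap); the matrix is the 2-D dot-plot of the
    sequence against itself and is symmetric with a unit diagonal.
    """
    if cap < 1:
        raise ValueError("cap must be positive")
    N = min(len(seq), cap)
    a = np.frombuffer(seq.bases[:N].encode("ascii"), dtype=np.uint8)
    return (a[:, None] == a[None, :]).astype(np.uint8)


def sigma_profile(mat: np.ndarray) -> np.ndarray:
    """sigma(n) for n = 2..N: mean 1-count over all contiguous n x n windows.

    Computed with 2-D prefix sums, the deterministic expectation of drawing
    submatrices at random. Entry k of the result is sigma(k + 2).
    """
    N = mat.shape[0]
    P = np.zeros((N + 1, N + 1), dtype=np.int64)
    P[1:, 1:] = np.cumsum(np.cumsum(mat, axis=0), axis=1)
    out = np.empty(N - 1, dtype=float)
    for n in range(2, N + 1):
        w = P[n:, n:] - P[:-n, n:] - P[n:, :-n] + P[:-n, :-n]
        out[n - 2] = w.mean()
    return out


def fractal_dimension(seq: NucleotideSequence, cap: int = DEFAULT_FD_CAP) -> float:
    """Indicator-matrix fractal dimension of the first min(L, cap) bases.

    FD = -(1/N) * sum_{n=2..N} log sigma(n) / log n, a ratio of logs and
    hence base-free. sigma(n) > 0 always (the diagonal is all ones), and the
    sign convention makes the value negative. Deterministic to the bit.
    """
    mat = indicator_matrix(seq, cap=cap)
    N = mat.shape[0]
    if N < 2:
        raise ValueError(f"fractal dimension requires at least 2 bases, got {N}")
    sig = sigma_profile(mat)
    n = np.arange(2, N + 1, dtype=float)
    return float(-(1.0 / N) * np.sum(np.log(sig) / np.log(n)))
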