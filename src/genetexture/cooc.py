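"""Nucleotide co-occurrence matrices and GLCM-style texture features.

A co-occurrence matrix tallies, for each row pattern (a 1-, 2- or 3-base
string) and each column base, how often the pattern occurs in the sequence
immediately followed by that base — the sequence analogue of a gray-level
co-occurrence matrix with a unit offset. Eight fixed pattern sets, named
I..P, cover the single bases, the repeated dinucleotides, the
ascending/descending mixed dinucleotides and four families of mixed
trinucleotides. Each matrix is normalized to sum to 1 and summarised by five
texture statistics (energy, entropy, homogeneity, contrast, dissimilarity),
giving 8 x 5 = 40 features per sequence.

Counting is an overlapping scan with step 1: position i contributes to cell
(r, s) when the m-mer at i equals row pattern r and the base at i + m is
column base s. For the single-base set I the grand total is therefore
exactly L - 1 (every adjacent pair counted once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seqio import NucleotideSequence

logger = logging.getLogger("genetexture")

#: Column order of every matrix.
COL_ALPHABET = ("A", "C", "T", "G")

_BASE_INDEX = {b: i for i, b in enumerate(COL_ALPHABET)}


@dataclass(frozen=True)
class PatternSet:
    """One of the eight fixed row-pattern sets I..P."""

    name: str
    row_patterns: tuple[str, ...]

    @property
    def pattern_length(self) -> int:
        return len(self.row_patterns[0])

    @property
    def n_rows(self) -> int:
        return len(self.row_patterns)


PATTERN_SETS: dict[str, PatternSet] = {
    "I": PatternSet("I", ("A", "C", "T", "G")),
    "J": PatternSet("J", ("AA", "CC", "TT", "GG")),
    "K": PatternSet("K", ("AC", "AT", "AG", "CT", "CG", "TG")),
    "L": PatternSet("L", ("CA", "TA", "GA", "TC", "GC", "GT")),
    "M": PatternSet("M", ("ACT", "ACG", "ATG", "CTG")),
    "N": PatternSet("N", ("CAT", "CAG", "TAG", "TCG")),
    "O": PatternSet("O", ("ATC", "AGC", "AGT", "CGT")),
    "P": PatternSet("P", ("TCA", "GCA", "GTA", "GTC")),
}

#: Matrix order defining the layout of the 40-dimensional vector.
MATRIX_ORDER = ("I", "J", "K", "L", "M", "N", "O", "P")

#: Per-matrix feature order.
TEXTURE_ORDER = ("energy", "entropy", "homogeneity", "contrast", "dissimilarity")


@dataclass(frozen=True)
class CoocMatrix:
    """Count matrix for one pattern set plus its normalized form.

    ``normalized`` is ``counts / counts.sum()``, or all-zero when the grand
    total is 0 (a sequence too short for the pattern length, or one in which
    no row pattern occurs).
    """

    pattern_set: PatternSet
    counts: np.ndarray

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


@dataclass(frozen=True)
class TextureFeatures:
    energy: float
    entropy: float
    homogeneity: float
    contrast: float
    dissimilarity: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in TEXTURE_ORDER], dtype=float
        )


def _encode(seq: NucleotideSequence) -> np.ndarray:
    return np.frombuffer(
        seq.bases.translate(str.maketrans("ACTG", "\x00\x01\x02\x03")).encode("latin-1"),
        dtype=np.uint8,
    ).astype(np.int64)


def _pattern_code(pattern: str) -> int:
    code = 0
    for b in pattern:
        code = code * 4 + _BASE_INDEX[b]
    return code


def count_cooc(seq: NucleotideSequence, pattern_set: PatternSet | str) -> CoocMatrix:
    """Count (row pattern, following base) co-occurrences in one sequence.

    Overlapping occurrences all count. Sequences shorter than
    ``pattern_length + 1`` yield an all-zero matrix (logged, not an error) so
    feature vectors stay total and fixed-length.
    """
    if isinstance(pattern_set, str):
        pattern_set = PATTERN_SETS[pattern_set]
    m = pattern_set.pattern_length
    q = pattern_set.n_rows
    L = len(seq)
    if L < m + 1:
        logger.warning(
            "sequence %r (length %d) shorter than %d; all-zero %s matrix",
            seq.id, L, m + 1, pattern_set.name,
        )
        return CoocMatrix(pattern_set, np.zeros((q, 4), dtype=np.int64))

    codes = _encode(seq)
    # joint code of the m-mer at i and the base at i+m, base-4
    joint = codes[: L - m].copy()
    for k in range(1, m + 1):
        joint = joint * 4 + codes[k : L - m + k]
    tally = np.bincount(joint, minlength=4 ** (m + 1))
    counts = np.zeros((q, 4), dtype=np.int64)
    for r, pat in enumerate(pattern_set.row_patterns):
        base = _pattern_code(pat) * 4
        counts[r, :] = tally[base : base + 4]
    return CoocMatrix(pattern_set, counts)


def texture_features(mat: CoocMatrix | np.ndarray) -> TextureFeatures:
    """Five texture statistics of a normalized co-occurrence matrix.

    Sums run over every cell of the q x 4 matrix with 0-based integer row and
    column indices in the (r - s) terms; entropy uses the natural log with
    the 0*ln(0) = 0 convention. An all-zero matrix yields all five features
    equal to 0.
    """
    G = mat.normalized if isinstance(mat, CoocMatrix) else np.asarray(mat, dtype=float)
    r = np.arange(G.shape[0])[:, None]
    s = np.arange(G.shape[1])[None, :]
    d = r - s
    energy = float(np.sum(G**2))
    nz = G > 0
    entropy = float(-np.sum(G[nz] * np.log(G[nz])))
    homogeneity = float(np.sum(G / (1.0 + d**2)))
    contrast = float(np.sum(G * d**2))
    dissimilarity = float(np.sum(G * np.abs(d)))
    return TextureFeatures(energy, entropy, homogeneity, contrast, dissimilarity)


def cooc_matrices(seq: NucleotideSequence) -> dict[str, CoocMatrix]:
    """All eight co-occurrence matrices of a sequence, keyed I..P."""
    return {name: count_cooc(seq, name) for name in MATRIX_ORDER}


def cooc_feature_vector(seq: NucleotideSequence) -> np.ndarray:
    """The 40-dimensional texture feature vector of a sequence.

    Concatenation over matrices I, J, K, L, M, N, O, P; within each matrix
    the order is (energy, entropy, homogeneity, contrast, dissimilarity).
    """
    blocks = [
        texture_features(count_cooc(seq, name)).as_array() for name in MATRIX_ORDER
    ]
    vec = np.concatenate(blocks)
    assert vec.shape == (40,)
    return vec
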