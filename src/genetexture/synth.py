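"""Synthetic multi-class DNA sequence generator with Markov transition structure.

Classes are defined by low-order Markov chains over {A, C, T, G}. Because the
co-occurrence texture features are statistics of (m+1)-mers with m <= 3,
order-1 and order-2 chains create exactly the kind of signal those features
can capture, while iid (uniform-transition) classes act as near-null
controls. Output mirrors a per-species-file corpus: one FASTA of all
sequences plus an ``id<TAB>label`` sidecar TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import NucleotideSequence, write_fasta

BASES = ("A", "C", "T", "G")


@dataclass(frozen=True)
class MarkovClassSpec:
    """Generative description of one sequence class.

    ``transition`` is row-stochastic: 4 x 4 for order 1 (rows indexed by the
    previous base) or 16 x 4 for order 2 (rows indexed by the previous
    dinucleotide, first base major, in A, C, T, G order).
    """

    class_label: str
    order: int
    initial_distribution: np.ndarray
    transition: np.ndarray
    n_sequences: int
    length_range: tuple[int, int]

    def __post_init__(self) -> None:
        init = np.asarray(self.initial_distribution, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        expected_rows = 4 if self.order == 1 else 16
        if trans.shape != (expected_rows, 4):
            raise ValueError(
                f"order-{self.order} transition must be {expected_rows}x4, got {trans.shape}"
            )
        if init.shape != (4,):
            raise ValueError("initial_distribution must have 4 entries")
        if (trans < 0).any() or (init < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(trans.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every transition row must sum to 1")
        if not np.isclose(init.sum(), 1.0, atol=1e-12):
            raise ValueError("initial_distribution must sum to 1")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= min <= max")
        object.__setattr__(self, "initial_distribution", init)
        object.__setattr__(self, "transition", trans)


def _sample_sequence(spec: MarkovClassSpec, length: int, rng: np.random.Generator) -> str:
    # inverse-CDF sampling against precomputed row CDFs; one uniform per base
    cum_init = np.cumsum(spec.initial_distribution)
    cum_trans = np.cumsum(spec.transition, axis=1)
    u = rng.random(length)
    idx = np.empty(length, dtype=np.int64)
    idx[0] = np.searchsorted(cum_init, u[0], side="right")
    if spec.order == 1:
        for t in range(1, length):
            idx[t] = cum_trans[idx[t - 1]].searchsorted(u[t], side="right")
    else:
        if length > 1:
            idx[1] = np.searchsorted(cum_init, u[1], side="right")
        for t in range(2, length):
            ctx = idx[t - 2] * 4 + idx[t - 1]
            idx[t] = cum_trans[ctx].searchsorted(u[t], side="right")
    idx = np.minimum(idx, 3)  # guard against u landing exactly on the CDF top
    return "".join(BASES[i] for i in idx)


def generate_sequences(
    specs: list[MarkovClassSpec], seed: int
) -> tuple[list[NucleotideSequence], list[str]]:
    """Sample all classes' sequences; deterministic given ``seed``.

    Sequence ids encode class and 1-based index (``<label>_<k>``). Returns
    the sequences and the parallel label list.
    """
    if not specs:
        raise ValueError("at least one class spec required")
    rng = np.random.default_rng(seed)
    seqs: list[NucleotideSequence] = []
    labels: list[str] = []
    for spec in specs:
        lo, hi = spec.length_range
        for k in range(1, spec.n_sequences + 1):
            length = int(rng.integers(lo, hi + 1))
            bases = _sample_sequence(spec, length, rng)
            seqs.append(NucleotideSequence(id=f"{spec.class_label}_{k}", bases=bases))
            labels.append(spec.class_label)
    return seqs, labels


def generate(
    specs: list[MarkovClassSpec],
    seed: int,
    out_fasta: str | Path,
    out_labels: str | Path,
) -> tuple[Path, Path]:
    """Write the sampled corpus as FASTA plus an id<TAB>label TSV."""
    seqs, labels = generate_sequences(specs, seed)
    out_fasta, out_labels = Path(out_fasta), Path(out_labels)
    write_fasta(seqs, out_fasta)
    with open(out_labels, "w") as fh:
        for s, lab in zip(seqs, labels):
            fh.write(f"{s.id}\t{lab}\n")
    return out_fasta, out_labels


def _order2_matrix(kind: str) -> np.ndarray:
    """Structured 16 x 4 transition matrices with distinct texture.

    ``repeat`` favours extending the current base (homopolymer-rich),
    ``alternate`` favours switching purine/pyrimidine class every step, and
    ``motif`` favours continuing ascending A->C->T->G ladders. Mixing weight
    0.55 on the structure keeps rows well inside the simplex while making
    the pairwise row-averaged total-variation distance large (>= 0.2).
    """
    uniform = np.full((16, 4), 0.25)
    structured = np.zeros((16, 4))
    for prev2 in range(4):
        for prev1 in range(4):
            row = prev2 * 4 + prev1
            if kind == "repeat":
                structured[row, prev1] = 1.0
            elif kind == "alternate":
                # purines are A (0), G (3); pyrimidines C (1), T (2)
                targets = (1, 2) if prev1 in (0, 3) else (0, 3)
                structured[row, targets[0]] = structured[row, targets[1]] = 0.5
            elif kind == "motif":
                structured[row, (prev1 + 1) % 4] = 1.0
            else:
                raise ValueError(kind)
    return 0.45 * uniform + 0.55 * structured


def default_benchmark_specs(
    n_per_class: tuple[int, int, int] = (150, 150, 150),
    length_range: tuple[int, int] = (300, 3000),
) -> list[MarkovClassSpec]:
    """Three order-2 classes whose transition structures are far apart.

    Defaults: 150 sequences per class, lengths uniform on [300, 3000]. The
    imbalanced variant of the benchmark passes ``n_per_class=(150, 50, 25)``.
    """
    uniform_init = np.full(4, 0.25)
    kinds = ("repeat", "alternate", "motif")
    labels = ("C1", "C2", "C3")
    return [
        MarkovClassSpec(
            class_label=lab,
            order=2,
            initial_distribution=uniform_init,
            transition=_order2_matrix(kind),
            n_sequences=n,
            length_range=length_range,
        )
        for lab, kind, n in zip(labels, kinds, n_per_class)
    ]


def null_specs(
    n_per_class: tuple[int, int, int] = (150, 150, 150),
    length_range: tuple[int, int] = (300, 3000),
) -> list[MarkovClassSpec]:
    """Three iid-uniform classes: no transition structure, a null control."""
    uniform_init = np.full(4, 0.25)
    uniform = np.full((4, 4), 0.25)
    return [
        MarkovClassSpec(
            class_label=lab,
            order=1,
            initial_distribution=uniform_init,
            transition=uniform,
            n_sequences=n,
            length_range=length_range,
        )
        for lab, n in zip(("C1", "C2", "C3"), n_per_class)
    ]


def transition_tv_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Row-averaged total-variation distance between two transition matrices."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(0.5 * np.abs(a - b).sum(axis=1).mean())
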