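"""FASTA input, purine/pyrimidine encoding and feature-table output.

Sequences are plain DNA strings over {A, C, G, T}. The binary encoding maps
purines (A, G) to 1 and pyrimidines (C, T) to 0; that 0/1 series is the input
to the entropy and Hurst estimators in :mod:`genetexture.classic`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("genetexture")

VALID_BASES = frozenset("ACGT")
PURINES = frozenset("AG")

AmbiguousPolicy = Literal["error", "drop-record", "strip-chars"]


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence over {A, C, G, T} with a record identifier."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class BinarySequence:
    """Purine/pyrimidine 0/1 encoding of a DNA sequence.

    ``p0`` and ``p1`` are the empirical symbol frequencies (counts / length),
    so ``p0 + p1 == 1`` exactly.
    """

    bits: np.ndarray
    p0: float = field(init=False)
    p1: float = field(init=False)

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or bits.size < 1:
            raise ValueError("bits must be a non-empty 1-D array")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        object.__setattr__(self, "bits", bits)
        n1 = int(bits.sum())
        object.__setattr__(self, "p1", n1 / bits.size)
        object.__setattr__(self, "p0", (bits.size - n1) / bits.size)

    def __len__(self) -> int:
        return int(self.bits.size)


def encode_binary(seq: NucleotideSequence) -> BinarySequence:
    """Encode a DNA sequence as bits: A,G -> 1 (purine), C,T -> 0 (pyrimidine)."""
    bits = np.fromiter((1 if b in PURINES else 0 for b in seq.bases),
                       dtype=np.int8, count=len(seq))
    return BinarySequence(bits)


def read_fasta(
    path: str | Path,
    ambiguous_policy: AmbiguousPolicy = "drop-record",
) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into validated nucleotide sequences.

    Bases are uppercased. Records containing characters outside {A, C, G, T}
    (N and other IUPAC ambiguity codes) are handled per ``ambiguous_policy``:

    - ``"error"``: raise on the first offending record;
    - ``"drop-record"`` (default): skip the record with a logged warning;
    - ``"strip-chars"``: delete the offending characters and keep the record
      (dropped entirely if nothing remains).

    Records are returned in file order. An empty or record-less file is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[NucleotideSequence] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        bases = str(rec.seq).upper()
        bad = set(bases) - VALID_BASES
        if bad:
            if ambiguous_policy == "error":
                raise ValueError(
                    f"record {rec.id!r} contains ambiguous characters {sorted(bad)}"
                )
            if ambiguous_policy == "drop-record":
                logger.warning(
                    "dropping record %r: ambiguous characters %s", rec.id, sorted(bad)
                )
                continue
            bases = "".join(b for b in bases if b in VALID_BASES)
            logger.warning("stripped ambiguous characters from record %r", rec.id)
        if not bases:
            logger.warning("dropping record %r: no valid bases remain", rec.id)
            continue
        records.append(NucleotideSequence(id=rec.id, bases=bases))
    if n_seen == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences to FASTA (used by the synthetic generator)."""
    recs = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>label`` sidecar TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], dtype=str)
    return dict(zip(df["id"], df["label"]))


def feature_names(n_features: int) -> list[str]:
    """Canonical column names: f1..f40, optionally followed by SE, HE, MSE, FD."""
    if n_features == 40:
        return [f"f{i}" for i in range(1, 41)]
    if n_features == 44:
        return [f"f{i}" for i in range(1, 41)] + ["SE", "HE", "MSE", "FD"]
    return [f"f{i}" for i in range(1, n_features + 1)]


def write_feature_table(
    records: Sequence[tuple[str, str, np.ndarray]],
    path: str | Path,
    n_features: int | None = None,
) -> None:
    """Write (id, label, feature-vector) records as a round-trippable CSV.

    All vectors must share one dimension. An empty record list writes a
    header-only file, for which ``n_features`` must be given.
    """
    if records:
        dims = {len(np.asarray(v).ravel()) for _, _, v in records}
        if len(dims) != 1:
            raise ValueError(f"feature vectors have mixed dimensions {sorted(dims)}")
        dim = dims.pop()
        if n_features is not None and n_features != dim:
            raise ValueError(f"n_features={n_features} but vectors have {dim}")
    elif n_features is None:
        raise ValueError("n_features required for an empty record list")
    else:
        dim = n_features
    cols = feature_names(dim)
    df = pd.DataFrame(
        [np.asarray(v, dtype=float).ravel() for _, _, v in records], columns=cols
    )
    df.insert(0, "label", [lab for _, lab, _ in records])
    df.insert(0, "id", [rid for rid, _, _ in records])
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV back; first two columns are id and label."""
    df = pd.read_csv(path, dtype={"id": str, "label": str})
    if list(df.columns[:2]) != ["id", "label"]:
        raise ValueError(f"{path}: expected leading 'id' and 'label' columns")
    return df
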