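"""Multiple-sequence-alignment I/O, filtering and one-hot encoding.

Alignments come in as FASTA or A3M (lowercase columns are insertions relative
to the query and are removed to restore a rectangular alignment).  The first
record is treated as the query throughout.  Filtering mirrors the standard
HHfilter-style redundancy reduction: a coverage floor followed by a greedy
maximum-pairwise-identity sweep in file order.

Coordinates are 0-based internally; anything printed for humans is 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import Alphabet, GAP_INDEX

__all__ = [
    "Msa",
    "OneHotMsa",
    "read_msa",
    "write_fasta",
    "filter_msa",
    "one_hot_encode",
    "decode_one_hot",
]


@dataclass
class Msa:
    """A rectangular alignment of N sequences of length L."""

    sequences: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        L = len(self.sequences[0])
        if L < 1:
            raise ValueError("alignment length must be at least 1")
        for k, s in enumerate(self.sequences):
            if len(s) != L:
                raise ValueError(
                    f"length mismatch: sequence {k + 1} has length {len(s)}, expected {L}"
                )
        if not self.ids:
            self.ids = [f"seq_{k}" for k in range(len(self.sequences))]
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")

    @property
    def N(self) -> int:
        return len(self.sequences)

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    def tokens(self, alphabet: Alphabet | None = None) -> np.ndarray:
        """Integer-encoded N x L token matrix (gaps are GAP_INDEX)."""
        alphabet = alphabet or Alphabet()
        return np.stack([alphabet.encode(s) for s in self.sequences])


@dataclass
class OneHotMsa:
    """One-hot encoded alignment X with shape (N, L, A).

    A residue at (n, i) gives a one-hot slice summing to 1; a gap gives an
    all-zero slice, so the alphabet stays at A = 20.
    """

    X: np.ndarray
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 3 or self.X.shape[2] != self.alphabet.size:
            raise ValueError("X must have shape (N, L, A)")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.X.shape[1]

    @property
    def A(self) -> int:
        return self.X.shape[2]


def _normalise_residues(seq: str, alphabet: Alphabet) -> str:
    """Uppercase and map any non-canonical residue character to gap."""
    allowed = set(alphabet.tokens)
    out = []
    for ch in seq.upper():
        if ch in allowed:
            out.append(ch)
        else:
            # X, B, Z, U, O, '.', '*', ... all become gaps
            out.append(alphabet.gap)
    return "".join(out)


def read_msa(path: str | Path, format: str = "fasta", alphabet: Alphabet | None = None) -> Msa:
    """Read a FASTA or A3M alignment into an :class:`Msa`.

    A3M lowercase characters are insertions relative to the query and are
    deleted; the result must be rectangular.  Residues are uppercased and
    unknown residue characters (``X`` and other non-canonical codes) map to
    gaps.  The first record is the query.
    """
    alphabet = alphabet or Alphabet()
    if format not in {"fasta", "a3m"}:
        raise ValueError(f"unknown alignment format: {format!r}")
    path = Path(path)
    with open(path) as fh:
        # quick structural check so errors can name a line
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path.name}:{lineno}: expected a '>' header as first record"
                    )
                break
        else:
            raise ValueError(f"{path.name}: no records found")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path.name}: no records found")
    ids, seqs = [], []
    for rec in records:
        raw = str(rec.seq)
        if format == "a3m":
            raw = "".join(ch for ch in raw if not ch.islower())
        ids.append(rec.id)
        seqs.append(_normalise_residues(raw, alphabet))
    L = len(seqs[0])
    for k, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError(
                f"{path.name}: record {ids[k]!r} has length {len(s)} after "
                f"normalisation, expected {L}"
            )
    return Msa(seqs, ids)


def write_fasta(msa: Msa, path: str | Path) -> None:
    """Emit an alignment as plain FASTA."""
    with open(path, "w") as fh:
        for name, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{name}\n{seq}\n")


def _pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of identical columns; columns where both are gaps are excluded."""
    both_gap = (a == GAP_INDEX) & (b == GAP_INDEX)
    denom = int((~both_gap).sum())
    if denom == 0:
        return 1.0
    matches = int(((a == b) & ~both_gap).sum())
    return matches / denom


def filter_msa(msa: Msa, max_identity: float = 0.9, min_coverage: float = 0.75) -> Msa:
    """Coverage then greedy identity filtering; the query is always retained.

    Sequences with a fraction of non-gap columns below ``min_coverage`` are
    removed first.  Remaining sequences are scanned in file order and dropped
    when their identity to any already-kept sequence exceeds ``max_identity``.
    """
    if not (0 < max_identity <= 1) or not (0 < min_coverage <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    toks = msa.tokens()
    coverage = (toks != GAP_INDEX).mean(axis=1)
    kept: list[int] = [0]  # query always survives
    for n in range(1, msa.N):
        if coverage[n] < min_coverage:
            continue
        if any(_pairwise_identity(toks[n], toks[k]) > max_identity for k in kept):
            continue
        kept.append(n)
    if len(kept) == 1 and msa.N > 1:
        warnings.warn("all non-query sequences removed by filtering", stacklevel=2)
    return Msa([msa.sequences[k] for k in kept], [msa.ids[k] for k in kept])


def one_hot_encode(msa: Msa, alphabet: Alphabet | None = None) -> OneHotMsa:
    """One-hot encode an alignment; gaps become all-zero slices."""
    alphabet = alphabet or Alphabet()
    toks = msa.tokens(alphabet)
    if (toks == -1).any():  # mask symbol has no place in an alignment
        n, i = np.argwhere(toks == -1)[0]
        raise ValueError(f"unexpected token in sequence {n + 1} at column {i + 1}")
    X = np.zeros((msa.N, msa.L, alphabet.size), dtype=np.float64)
    n_idx, l_idx = np.nonzero(toks >= 0)
    X[n_idx, l_idx, toks[n_idx, l_idx]] = 1.0
    return OneHotMsa(X, alphabet)


def decode_one_hot(encoded: OneHotMsa, ids: list[str] | None = None) -> Msa:
    """Inverse of :func:`one_hot_encode` (all-zero slices decode to gaps)."""
    occupied = encoded.X.sum(axis=2) > 0
    toks = np.where(occupied, encoded.X.argmax(axis=2), GAP_INDEX)
    seqs = [encoded.alphabet.decode(row) for row in toks]
    return Msa(seqs, ids or [])
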