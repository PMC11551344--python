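"""Residue alphabet shared by every module.

The toolkit works on the 20 canonical amino acids (A = 20).  Gaps and mask
tokens are *not* part of the one-hot alphabet: a gap encodes as an all-zero
one-hot slice, and a mask marks a position hidden from a model.  Integer
token arrays use ``MASK_INDEX`` / ``GAP_INDEX`` sentinels for these states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The 20 canonical amino acids in alphabetical one-letter order.
CANONICAL_AAS = "ACDEFGHIKLMNPQRSTVWY"

#: Sentinel token indices used in integer-encoded sequences.
MASK_INDEX = -1
GAP_INDEX = -2


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue tokens plus the special symbols used in text I/O.

    Parameters
    ----------
    tokens:
        Residue symbols, one character each.  Exactly 20 for proteins.
    mask, bos, eos, gap:
        Special symbols; none may collide with a residue token.
    """

    tokens: str = CANONICAL_AAS
    mask: str = "#"
    bos: str = "<"
    eos: str = ">"
    gap: str = "-"

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("residue tokens must be unique")
        specials = {self.mask, self.bos, self.eos, self.gap}
        if len(specials) != 4:
            raise ValueError("special tokens must be distinct")
        if specials & set(self.tokens):
            raise ValueError("special tokens must not collide with residues")

    @property
    def size(self) -> int:
        """Number of residue tokens, A."""
        return len(self.tokens)

    def index(self, char: str) -> int:
        """Token index of a residue character (raises KeyError if unknown)."""
        i = self.tokens.find(char)
        if i < 0:
            raise KeyError(f"not a residue token: {char!r}")
        return i

    def encode(self, sequence: str) -> np.ndarray:
        """Integer-encode a sequence string.

        Residues map to ``0..A-1``, the mask symbol to :data:`MASK_INDEX`
        and the gap symbol to :data:`GAP_INDEX`.  Any other character is an
        error; normalise unknown residues upstream (see :func:`~coevjac.msa.read_msa`).
        """
        out = np.empty(len(sequence), dtype=np.int64)
        for pos, ch in enumerate(sequence):
            if ch == self.mask:
                out[pos] = MASK_INDEX
            elif ch == self.gap:
                out[pos] = GAP_INDEX
            else:
                try:
                    out[pos] = self.index(ch)
                except KeyError as exc:
                    raise ValueError(
                        f"unknown token {ch!r} at position {pos + 1} (1-based)"
                    ) from exc
        return out

    def decode(self, tokens: np.ndarray) -> str:
        """Inverse of :meth:`encode`."""
        chars = []
        for t in np.asarray(tokens, dtype=np.int64):
            if t == MASK_INDEX:
                chars.append(self.mask)
            elif t == GAP_INDEX:
                chars.append(self.gap)
            else:
                chars.append(self.tokens[int(t)])
        return "".join(chars)

    def one_hot(self, tokens: np.ndarray) -> np.ndarray:
        """One-hot rows for an integer token array; sentinels give zero rows."""
        tokens = np.asarray(tokens, dtype=np.int64)
        X = np.zeros((tokens.size, self.size), dtype=np.float64)
        valid = tokens >= 0
        X[np.nonzero(valid)[0], tokens[valid]] = 1.0
        return X
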