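"""Analytic fixture models and synthetic data generators.

Everything here exists so the rest of the toolkit is testable offline with
known ground truth:

* :class:`LinearLogitModel` — an MRF/MG-style linear logit model whose
  categorical Jacobian provably equals its own coupling tensor (the oracle
  for the Jacobian extraction).
* :class:`QuantizedLinearLogitModel` — a saturating variant whose output is
  rounded to a resolution grid, so infinitesimal input perturbations vanish
  while unit (categorical-like) steps still read out the couplings.
* :class:`PottsModel` + :func:`sample_potts_msa` — Gibbs sampling of
  synthetic alignments with planted couplings, the ground truth for the MG
  estimator's parameter-recovery tests.
* :class:`SyntheticContactModel` — a contact model with a controllable local
  context requirement, the test implementation for the masked contact-
  recovery experiments.

All randomness flows through explicitly passed seeds or generators; fixtures
never touch global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import MASK_INDEX, Alphabet
from .couplings import ContactMap, CouplingTensor
from .jacobian import center_blocks, symmetrize
from .msa import Msa

__all__ = [
    "random_zero_sum_couplings",
    "PottsModel",
    "make_planted_potts",
    "LinearLogitModel",
    "make_linear_logit_model",
    "QuantizedLinearLogitModel",
    "sample_potts_tokens",
    "sample_potts_msa",
    "SyntheticContactModel",
    "make_synthetic_contact_model",
]

GAUGE_TOL = 1e-8


def _check_gauge(W: np.ndarray, tol: float = GAUGE_TOL) -> None:
    L = W.shape[0]
    if np.abs(W[np.arange(L), :, np.arange(L), :]).max() > tol:
        raise ValueError("self-coupling blocks must be zero")
    if np.abs(W - W.transpose(2, 3, 0, 1)).max() > tol:
        raise ValueError("coupling tensor must be symmetric")
    if max(np.abs(W.mean(axis=1)).max(), np.abs(W.mean(axis=3)).max()) > tol:
        raise ValueError("coupling tensor must be in the zero-sum gauge")


def random_zero_sum_couplings(
    L: int, A: int = 20, rng: np.random.Generator | int | None = None, scale: float = 1.0
) -> np.ndarray:
    """Random symmetric zero-sum-gauge coupling tensor with zero diagonal blocks."""
    rng = np.random.default_rng(rng)
    W = scale * rng.standard_normal((L, A, L, A))
    W[np.arange(L), :, np.arange(L), :] = 0.0
    W = symmetrize(W)
    W = center_blocks(W)
    W[np.arange(L), :, np.arange(L), :] = 0.0
    return W


@dataclass
class PottsModel:
    """Markov random field over aligned sequences: fields h (L, A) and a
    symmetric, zero-sum-gauge coupling tensor W (L, A, L, A)."""

    h: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.h.shape != self.W.shape[:2]:
            raise ValueError("field and coupling shapes disagree")
        _check_gauge(self.W)

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def A(self) -> int:
        return self.h.shape[1]

    def coupling_tensor(self) -> CouplingTensor:
        return CouplingTensor(self.W, source_tag="linear")


def make_planted_potts(
    L: int,
    n_pairs: int = 5,
    A: int = 20,
    strength: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[PottsModel, list[tuple[int, int]]]:
    """Potts model with couplings planted at ``n_pairs`` disjoint position pairs.

    Each planted 20x20 block is standard-normal noise scaled by ``strength``
    and projected to the zero-sum gauge; fields are zero so single-site
    marginals stay near uniform.  Returns the model and the sorted list of
    planted pairs (i < j).
    """
    if 2 * n_pairs > L:
        raise ValueError("too many pairs for the sequence length")
    rng = np.random.default_rng(rng)
    positions = rng.choice(L, size=2 * n_pairs, replace=False)
    pairs = sorted(
        tuple(sorted((int(positions[2 * k]), int(positions[2 * k + 1]))))
        for k in range(n_pairs)
    )
    W = np.zeros((L, A, L, A))
    for i, j in pairs:
        B = strength * rng.standard_normal((A, A))
        B = B - B.mean(axis=0) - B.mean(axis=1, keepdims=True) + B.mean()
        W[i, :, j, :] = B
        W[j, :, i, :] = B.T
    return PottsModel(np.zeros((L, A)), W), pairs


class LinearLogitModel:
    """Linear (MRF/MG-style) logit model: logits[j, b] = h[j, b] + sum_i W[j, b, i, x_i].

    Masked positions contribute nothing — exactly the token-axis mean in the
    zero-sum gauge.  The coupling tensor must be symmetric, zero-sum gauge,
    with zero diagonal blocks, otherwise the categorical-Jacobian identity
    (Jacobian == W) would silently fail.
    """

    supports_soft = True

    def __init__(self, W: np.ndarray, h: np.ndarray | None = None):
        W = np.asarray(W, dtype=np.float64)
        _check_gauge(W)
        self.W = W
        self.h = (
            np.zeros(W.shape[:2]) if h is None else np.asarray(h, dtype=np.float64)
        )
        if self.h.shape != W.shape[:2]:
            raise ValueError("field shape must be (L, A)")

    @property
    def L(self) -> int:
        return self.W.shape[0]

    def evaluate(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.size != self.L:
            raise ValueError(f"expected length {self.L}, got {tokens.size}")
        out = self.h.copy()
        pos = np.nonzero(tokens >= 0)[0]
        if pos.size:
            # W[:, :, i, x_i] summed over occupied positions i
            out += self.W[:, :, pos, tokens[pos]].sum(axis=-1)
        return out

    def evaluate_soft(self, distribution: np.ndarray) -> np.ndarray:
        P = np.asarray(distribution, dtype=np.float64)
        if P.shape != self.W.shape[:2]:
            raise ValueError("distribution must have shape (L, A)")
        return self.h + np.einsum("jbia,ia->jb", self.W, P)


def make_linear_logit_model(W, h=None) -> LinearLogitModel:
    """Factory mirroring the class constructor (kept for API symmetry)."""
    W = W.W if isinstance(W, CouplingTensor) else W
    return LinearLogitModel(W, h)


class QuantizedLinearLogitModel(LinearLogitModel):
    """Linear model whose logits are rounded to a ``resolution`` grid.

    The quantizer is a hard saturating nonlinearity: perturbations that move
    a logit by less than resolution/2 leave the output unchanged, so a
    finite-difference Jacobian with a tiny step reads out nothing while the
    categorical (unit) perturbation still recovers the couplings.
    """

    def __init__(self, W, h=None, resolution: float = 0.1):
        super().__init__(W, h)
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = resolution

    def _quantize(self, z: np.ndarray) -> np.ndarray:
        return np.round(z / self.resolution) * self.resolution

    def evaluate(self, tokens):
        return self._quantize(super().evaluate(tokens))

    def evaluate_soft(self, distribution):
        return self._quantize(super().evaluate_soft(distribution))


def sample_potts_tokens(
    model: PottsModel, n_sequences: int, n_sweeps: int = 20, seed: int = 0
) -> np.ndarray:
    """Gibbs-sample token matrices (n_sequences, L) from a Potts model.

    Each sequence is an independent chain: uniform random start, then
    ``n_sweeps`` full passes resampling every position from its conditional
    softmax(h[i, :] + sum_{j != i} W[i, :, j, x_j]).  Deterministic for a
    fixed seed.
    """
    if n_sweeps < 1:
        raise ValueError("need at least one sweep")
    rng = np.random.default_rng(seed)
    L, A = model.L, model.A
    x = rng.integers(0, A, size=(n_sequences, L))
    # W[i] transposed to (j, token_at_j, a) for vectorised gathering
    W_gather = [model.W[i].transpose(1, 2, 0) for i in range(L)]
    cols = np.arange(L)
    for _ in range(n_sweeps):
        for i in range(L):
            # contribution of every context position j (self-block is zero)
            contrib = W_gather[i][cols[None, :], x, :].sum(axis=1)
            logits = model.h[i] + contrib
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n_sequences)
            x[:, i] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return x


def sample_potts_msa(
    model: PottsModel,
    n_sequences: int,
    n_sweeps: int = 20,
    seed: int = 0,
    alphabet: Alphabet | None = None,
) -> Msa:
    """Gibbs-sample a gap-free alignment (see :func:`sample_potts_tokens`)."""
    alphabet = alphabet or Alphabet()
    if model.A != alphabet.size:
        raise ValueError("model alphabet size must match the residue alphabet")
    toks = sample_potts_tokens(model, n_sequences, n_sweeps, seed)
    seqs = [alphabet.decode(row) for row in toks]
    return Msa(seqs, [f"sample_{k}" for k in range(n_sequences)])


@dataclass
class SyntheticContactModel:
    """Contact model with a tunable local-context requirement.

    A position is *supported* when at least ``context_window`` residues
    within +/- ``context_window`` of it (excluding itself) are unmasked.
    ``contacts`` returns ``base_map[i, j]`` when both i and j are supported,
    else 0.  With a fully unmasked sequence of length > context_window the
    output equals ``base_map`` exactly.  Deterministic.
    """

    base_map: np.ndarray
    context_window: int

    def __post_init__(self) -> None:
        base = self.base_map.C if isinstance(self.base_map, ContactMap) else self.base_map
        base = np.asarray(base, dtype=np.float64)
        if base.ndim != 2 or base.shape[0] != base.shape[1]:
            raise ValueError("base map must be square")
        if (base < 0).any() or (base > 1).any():
            raise ValueError("base map entries must lie in [0, 1]")
        if np.abs(base - base.T).max() > 1e-12:
            raise ValueError("base map must be symmetric")
        if self.context_window < 1:
            raise ValueError("context_window must be positive")
        self.base_map = base

    @property
    def L(self) -> int:
        return self.base_map.shape[0]

    def contacts(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.size != self.L:
            raise ValueError(f"expected length {self.L}, got {tokens.size}")
        unmasked = (tokens != MASK_INDEX).astype(np.int64)
        w = self.context_window
        window = np.convolve(unmasked, np.ones(2 * w + 1, dtype=np.int64), mode="same")
        supported = (window - unmasked) >= w
        return self.base_map * np.outer(supported, supported)


def make_synthetic_contact_model(base_map, context_window: int) -> SyntheticContactModel:
    return SyntheticContactModel(base_map, context_window)
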