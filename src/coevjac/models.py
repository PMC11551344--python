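"""Behavioural contracts for the models being interrogated.

A *logit model* maps a (possibly partially masked) token sequence to per-
position residue logits; any sequence model — a protein language model, an
MRF, an MG model — fits the contract.  A *contact model* maps a masked token
sequence to an L x L contact-probability matrix.  Fixture implementations
live in :mod:`coevjac.fixtures`; adapters for external pretrained models in
:mod:`coevjac.adapters`.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class LogitModel(Protocol):
    """sequence -> L x A logits.

    ``evaluate`` takes an integer token array (residues ``0..A-1``, masked
    positions :data:`~coevjac.alphabet.MASK_INDEX`) and must be deterministic
    with output shape (L, A).  Models that can score *soft* (relaxed,
    non-one-hot) inputs set ``supports_soft`` and implement
    ``evaluate_soft``, which enables the finite-difference Jacobian.
    """

    supports_soft: bool

    def evaluate(self, tokens: np.ndarray) -> np.ndarray: ...

    def evaluate_soft(self, distribution: np.ndarray) -> np.ndarray: ...


@runtime_checkable
class ContactModel(Protocol):
    """masked sequence -> symmetric L x L contact probabilities in [0, 1]."""

    def contacts(self, tokens: np.ndarray) -> np.ndarray: ...


class ModelContractError(RuntimeError):
    """A model broke its behavioural contract (e.g. wrong output shape)."""


class SoftInputUnsupportedError(RuntimeError):
    """Raised when a finite-difference Jacobian is requested from a model
    without soft-input support; use the categorical Jacobian instead."""
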