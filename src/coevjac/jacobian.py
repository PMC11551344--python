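"""Categorical and finite-difference Jacobians of a sequence model.

The categorical Jacobian is an in-silico deep mutational scan: mutate every
position i to every residue a, record how the full logit matrix moves, and
collect the responses into a four-index tensor

    J[i, a, j, b] = f(X with x_i -> a)[j, b] - f(X)[j, b],

using 1 + L*A model evaluations in total.  Applied to a linear model (MRF or
MG) this returns the model's own pairwise coupling tensor exactly, which
makes the couplings of a nonlinear language model directly comparable to
classical coevolution estimates.

Post-processing fixes the gauge: each 20x20 block is mean-centered over both
token axes (removing the reference-token offset inherent in the
difference-from-original construction), then the tensor is symmetrized by
averaging with its (j, b, i, a) transpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import Alphabet
from .couplings import ContactMap, CouplingTensor, contact_map_from_couplings
from .models import LogitModel, ModelContractError, SoftInputUnsupportedError

__all__ = [
    "JacobianTensor",
    "center_blocks",
    "symmetrize",
    "categorical_jacobian",
    "numeric_jacobian",
    "contact_map_from_jacobian",
]


@dataclass
class JacobianTensor:
    """Jacobian J with shape (L, A, L, A) plus post-processing flags."""

    J: np.ndarray
    centered: bool = False
    symmetrized: bool = False

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.J.ndim != 4 or self.J.shape[0] != self.J.shape[2] or self.J.shape[1] != self.J.shape[3]:
            raise ValueError("J must have shape (L, A, L, A)")

    @property
    def L(self) -> int:
        return self.J.shape[0]

    @property
    def A(self) -> int:
        return self.J.shape[1]


def center_blocks(T: np.ndarray) -> np.ndarray:
    """Double-center every (i, j) block over both token axes.

    After centering, the mean over each token axis of every block is zero —
    the zero-sum gauge.  Idempotent.
    """
    row = T.mean(axis=1, keepdims=True)
    col = T.mean(axis=3, keepdims=True)
    grand = T.mean(axis=(1, 3), keepdims=True)
    return T - row - col + grand


def symmetrize(T: np.ndarray) -> np.ndarray:
    """Average with the joint-index transpose; a projection onto the
    symmetric subspace (closest symmetric tensor in Frobenius norm)."""
    return 0.5 * (T + T.transpose(2, 3, 0, 1))


def _postprocess(raw: np.ndarray, center: bool, do_symmetrize: bool) -> JacobianTensor:
    out = raw
    if center:
        out = center_blocks(out)
    if do_symmetrize:
        out = symmetrize(out)
    return JacobianTensor(out, centered=center, symmetrized=do_symmetrize)


def _encode(sequence, alphabet: Alphabet) -> np.ndarray:
    if isinstance(sequence, str):
        return alphabet.encode(sequence)
    return np.asarray(sequence, dtype=np.int64)


def _check_shape(logits: np.ndarray, L: int, A: int) -> np.ndarray:
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape != (L, A):
        raise ModelContractError(
            f"model returned shape {logits.shape}, expected ({L}, {A})"
        )
    return logits


def categorical_jacobian(
    model: LogitModel,
    sequence,
    alphabet: Alphabet | None = None,
    center: bool = True,
    symmetrize_output: bool = True,
) -> JacobianTensor:
    """Categorical Jacobian of ``model`` at ``sequence``.

    ``sequence`` may be a residue string (mask symbols allowed, for masked-
    context Jacobians) or an integer token array.  Mutated positions always
    receive residue tokens.  Runs exactly 1 + L*A model evaluations.
    """
    alphabet = alphabet or Alphabet()
    tokens = _encode(sequence, alphabet)
    L, A = tokens.size, alphabet.size
    f0 = _check_shape(model.evaluate(tokens), L, A)
    J = np.empty((L, A, L, A), dtype=np.float64)
    for i in range(L):
        for a in range(A):
            mutant = tokens.copy()
            mutant[i] = a
            J[i, a] = _check_shape(model.evaluate(mutant), L, A) - f0
    return _postprocess(J, center, symmetrize_output)


def numeric_jacobian(
    model: LogitModel,
    sequence,
    step: float = 1.0,
    alphabet: Alphabet | None = None,
    center: bool = True,
    symmetrize_output: bool = True,
) -> JacobianTensor:
    """Finite-difference Jacobian with a tunable perturbation step.

    Adds ``step`` to one entry of the one-hot input at a time and divides the
    logit response by the step.  On a linear model every step size gives the
    same (post-processed) answer as the categorical Jacobian; on saturating
    models small steps under-perturb and a large step (the default, 1.0, the
    categorical-like end of the range) is required.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not getattr(model, "supports_soft", False):
        raise SoftInputUnsupportedError(
            "model does not accept soft inputs; use categorical_jacobian instead"
        )
    alphabet = alphabet or Alphabet()
    tokens = _encode(sequence, alphabet)
    L, A = tokens.size, alphabet.size
    P = alphabet.one_hot(tokens)
    f0 = _check_shape(model.evaluate_soft(P), L, A)
    J = np.empty((L, A, L, A), dtype=np.float64)
    for i in range(L):
        for a in range(A):
            Q = P.copy()
            Q[i, a] += step
            J[i, a] = (_check_shape(model.evaluate_soft(Q), L, A) - f0) / step
    return _postprocess(J, center, symmetrize_output)


def contact_map_from_jacobian(jacobian: JacobianTensor, apply_apc: bool = True) -> ContactMap:
    """Contact map from a processed Jacobian: same Frobenius + APC pipeline
    as for MG couplings, over the 20 residue channels."""
    if not (jacobian.centered and jacobian.symmetrized):
        raise ValueError("Jacobian must be centered and symmetrized first")
    return contact_map_from_couplings(
        CouplingTensor(jacobian.J, source_tag="jacobian"), apply_apc=apply_apc
    )
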