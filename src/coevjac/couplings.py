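"""Linear (multivariate-Gaussian) coupling estimation and contact maps.

The MG estimator treats one-hot residues as continuous variables: flatten the
alignment to an N x (L*A) matrix, mean-center it, and take the negative
inverse of the shrunk empirical covariance,

    W = -(Cov(X_hat) + (4.5 / N) I)^{-1},

reshaped to a four-index coupling tensor [L, A, L, A].  The 4.5/N ridge keeps
the inverse well defined even when N < L*A.  Contact scores are per-pair
Frobenius norms of the 20x20 coupling blocks, background-corrected with the
average product correction (APC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .msa import OneHotMsa

__all__ = [
    "CouplingTensor",
    "ContactMap",
    "estimate_couplings_mg",
    "apc",
    "contact_map_from_couplings",
    "estimate_parameter_budget",
    "save_coupling_tensor",
    "load_coupling_tensor",
    "contact_map_to_tsv",
]

#: Empirically estimated shrinkage constant of the MG estimator.
SHRINKAGE = 4.5


@dataclass
class CouplingTensor:
    """Pairwise coupling weights W with shape (L, A, L, A).

    ``source_tag`` records provenance: ``"linear"`` (MG estimate),
    ``"jacobian"`` (categorical Jacobian) or ``"numeric"`` (finite
    differences).
    """

    W: np.ndarray
    source_tag: str = "linear"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 4 or self.W.shape[0] != self.W.shape[2] or self.W.shape[1] != self.W.shape[3]:
            raise ValueError("W must have shape (L, A, L, A)")
        if not np.isfinite(self.W).all():
            raise ValueError("coupling tensor contains non-finite entries")

    @property
    def L(self) -> int:
        return self.W.shape[0]

    @property
    def A(self) -> int:
        return self.W.shape[1]


@dataclass
class ContactMap:
    """Symmetric L x L matrix of contact scores or probabilities."""

    C: np.ndarray
    apc_applied: bool = False

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("contact map must be square")

    @property
    def L(self) -> int:
        return self.C.shape[0]


def estimate_couplings_mg(encoded: OneHotMsa) -> CouplingTensor:
    """Estimate the coupling tensor from a one-hot alignment.

    Requires N >= 2.  The covariance uses the 1/N normalisation; the
    shrinkage ridge 4.5/N dominates the 1/N-vs-1/(N-1) distinction.
    """
    N, L, A = encoded.X.shape
    if N < 2:
        raise ValueError(f"need at least 2 sequences, got {N}")
    F = encoded.X.reshape(N, L * A)
    Fc = F - F.mean(axis=0)
    cov = (Fc.T @ Fc) / N
    shrunk = cov + (SHRINKAGE / N) * np.eye(L * A)
    try:
        W = -scipy.linalg.inv(shrunk, check_finite=True)
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise ValueError("covariance inversion failed") from exc
    return CouplingTensor(W.reshape(L, A, L, A), source_tag="linear")


def apc(m: np.ndarray) -> np.ndarray:
    """Average product correction: m_ij - (row_i * col_j) / total.

    Exactly cancels rank-1 structure; output rows and columns sum to zero
    for any input.  A zero matrix passes through unchanged.
    """
    m = np.asarray(m, dtype=np.float64)
    total = m.sum()
    if total == 0:
        return m.copy()
    return m - np.outer(m.sum(axis=1), m.sum(axis=0)) / total


def contact_map_from_couplings(couplings: CouplingTensor, apply_apc: bool = True) -> ContactMap:
    """Frobenius-norm contact map of a coupling tensor, optionally APC-corrected.

    Raw entry m_ij is the Frobenius norm of the 20x20 block W[i, :, j, :];
    diagonal blocks (i == j) are excluded by zeroing the diagonal before the
    correction.
    """
    W = couplings.W
    m = np.sqrt(np.einsum("ianb,ianb->in", W, W))
    np.fill_diagonal(m, 0.0)
    if apply_apc:
        return ContactMap(apc(m), apc_applied=True)
    return ContactMap(m, apc_applied=False)


def estimate_parameter_budget(
    n_families: int, length: int, mode: str = "all_pairs", k: int | None = None
) -> float:
    """Parameter count for storing pairwise coevolutionary statistics.

    ``all_pairs`` charges every position pair of every family 20x20 = 400
    weights: n_families * C(length, 2) * 400.  ``k_contacts`` assumes each
    position touches at most k partners, each contact counted once:
    n_families * length * k / 2 * 400.
    """
    if n_families < 1 or length < 1:
        raise ValueError("counts must be positive")
    if mode == "all_pairs":
        return float(n_families) * (length * (length - 1) // 2) * 400.0
    if mode == "k_contacts":
        if k is None or k < 1:
            raise ValueError("k_contacts mode requires positive k")
        return float(n_families) * length * k / 2.0 * 400.0
    raise ValueError(f"unknown mode: {mode!r}")


def save_coupling_tensor(couplings: CouplingTensor, path: str | Path) -> None:
    """Serialise to a compressed .npz with a JSON index sidecar."""
    path = Path(path)
    np.savez_compressed(path, W=couplings.W)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"shape": list(couplings.W.shape), "source_tag": couplings.source_tag})
    )


def load_coupling_tensor(path: str | Path) -> CouplingTensor:
    path = Path(path)
    with np.load(path) as data:
        W = data["W"]
    sidecar = path.with_suffix(path.suffix + ".json")
    tag = "linear"
    if sidecar.exists():
        tag = json.loads(sidecar.read_text()).get("source_tag", "linear")
    return CouplingTensor(W, source_tag=tag)


def contact_map_to_tsv(cmap: ContactMap, path: str | Path) -> None:
    """Write i, j, score rows (1-based, upper triangle) as TSV."""
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        L = cmap.L
        for i in range(L):
            for j in range(i + 1, L):
                fh.write(f"{i + 1}\t{j + 1}\t{cmap.C[i, j]:.10g}\n")
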