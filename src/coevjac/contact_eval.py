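"""Contact-prediction evaluation against structures and between methods.

Structure contacts are residue pairs whose alpha-carbon distance is strictly
below a threshold (default 10 A).  Predicted maps are scored by precision of
the top floor(L/2) long-range pairs (sequence separation greater than 24
residues).  Coupling tensors from two methods are compared by Spearman
correlation of their top-pair 20x20 blocks under a family of magnitude
cutoffs b * SD, b in [0, 4].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import spearmanr

from .couplings import ContactMap, CouplingTensor, contact_map_from_couplings
from .jacobian import JacobianTensor, center_blocks

__all__ = [
    "StructureContacts",
    "structure_contacts",
    "ca_coordinates_from_pdb",
    "precision_at_topk",
    "precision_at_l2",
    "CouplingComparison",
    "compare_coupling_tensors",
    "comparison_to_tsv",
]


@dataclass
class StructureContacts:
    """Ground-truth contacts: unordered 0-based pairs plus a resolved mask."""

    pairs: frozenset
    L: int
    resolved_mask: np.ndarray

    def __post_init__(self) -> None:
        self.resolved_mask = np.asarray(self.resolved_mask, dtype=bool)
        for i, j in self.pairs:
            if i == j or not (0 <= i < self.L and 0 <= j < self.L):
                raise ValueError(f"invalid contact pair ({i}, {j})")


def structure_contacts(
    coords: np.ndarray,
    threshold: float = 10.0,
    resolved: np.ndarray | None = None,
) -> StructureContacts:
    """Contacts from per-residue alpha-carbon coordinates.

    ``coords`` is (L, 3); rows with non-finite values count as unresolved, as
    do positions where ``resolved`` is False.  Pair (i, j) is a contact iff
    both residues are resolved and their distance is strictly below
    ``threshold``.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (L, 3)")
    L = coords.shape[0]
    mask = np.isfinite(coords).all(axis=1)
    if resolved is not None:
        mask &= np.asarray(resolved, dtype=bool)
    if mask.sum() < 2:
        warnings.warn("fewer than 2 resolved residues; no contacts", stacklevel=2)
        return StructureContacts(frozenset(), L, mask)
    idx = np.nonzero(mask)[0]
    D = squareform(pdist(coords[idx]))
    pairs = set()
    for a in range(idx.size):
        for b in range(a + 1, idx.size):
            if D[a, b] < threshold:
                pairs.add((int(idx[a]), int(idx[b])))
    return StructureContacts(frozenset(pairs), L, mask)


def ca_coordinates_from_pdb(
    path: str | Path, chain: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Alpha-carbon coordinates from a PDB file (first model, altloc 'A').

    Returns (coords, resolved) spanning residue ids 1..max: rows for residues
    missing from the structure are NaN with ``resolved`` False.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    structure = PDBFile.read(str(path)).get_structure(model=1, altloc="first")
    sel = struc.filter_amino_acids(structure) & (structure.atom_name == "CA")
    if chain is not None:
        sel &= structure.chain_id == chain
    atoms = structure[sel]
    if atoms.array_length() == 0:
        raise ValueError(f"no CA atoms found in {path}")
    res_ids = atoms.res_id
    L = int(res_ids.max())
    coords = np.full((L, 3), np.nan)
    resolved = np.zeros(L, dtype=bool)
    for k in range(atoms.array_length()):
        r = int(res_ids[k]) - 1
        if r >= 0 and not resolved[r]:
            coords[r] = atoms.coord[k]
            resolved[r] = True
    return coords, resolved


def _ranked_pairs(C: np.ndarray, eligible: list[tuple[int, int]]):
    # descending score, ties broken by ascending (i, j)
    return sorted(eligible, key=lambda p: (-C[p[0], p[1]], p[0], p[1]))


def precision_at_topk(
    predicted: ContactMap,
    truth: StructureContacts,
    k: int,
    min_separation: int = 24,
) -> float:
    """Precision of the top-k predicted long-range contacts.

    Pairs with sequence separation |i - j| <= ``min_separation`` are excluded
    ("more than 24 residues" keeps |i - j| >= 25), as are pairs touching
    unresolved residues.  Ties in score break by ascending (i, j).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    L = predicted.L
    mask = truth.resolved_mask
    eligible = [
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if j - i > min_separation and mask[i] and mask[j]
    ]
    if not eligible:
        warnings.warn("no eligible long-range pairs", stacklevel=2)
        return float("nan")
    if len(eligible) < k:
        warnings.warn(
            f"only {len(eligible)} eligible pairs for top-{k}; using all", stacklevel=2
        )
        k = len(eligible)
    top = _ranked_pairs(predicted.C, eligible)[:k]
    hits = sum(1 for p in top if p in truth.pairs)
    return hits / k


def precision_at_l2(
    predicted: ContactMap, truth: StructureContacts, min_separation: int = 24
) -> float:
    """Long-range P@L/2: convenience wrapper with k = floor(L/2)."""
    return precision_at_topk(predicted, truth, k=truth.L // 2, min_separation=min_separation)


@dataclass
class CouplingComparison:
    """Spearman correlation between two coupling tensors across SD cutoffs."""

    cutoffs: np.ndarray
    rho: np.ndarray  # NaN where undefined
    n_retained: np.ndarray

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=np.float64)
        self.rho = np.asarray(self.rho, dtype=np.float64)
        self.n_retained = np.asarray(self.n_retained, dtype=np.int64)


def compare_coupling_tensors(
    W_linear: CouplingTensor,
    J: JacobianTensor | CouplingTensor,
    n_top_pairs: int | None = None,
    cutoffs=None,
) -> CouplingComparison:
    """Correlate the strongest coupling blocks of two methods.

    Select the top ``n_top_pairs`` (default L) position pairs by the linear
    model's APC contact map, gather both tensors' 20x20 blocks for those
    pairs, mean-center each block over both token axes, and report the
    Spearman rho over entries whose linear-model magnitude exceeds
    b * SD(linear entries) for each cutoff b.  Cutoffs retaining fewer than 3
    entries yield NaN with a warning.
    """
    J_arr = J.J if isinstance(J, JacobianTensor) else J.W
    if J_arr.shape != W_linear.W.shape:
        raise ValueError("tensor shapes disagree")
    L = W_linear.L
    n_top_pairs = n_top_pairs or L
    if cutoffs is None:
        cutoffs = np.arange(0.0, 4.5, 0.5)
    cmap = contact_map_from_couplings(W_linear, apply_apc=True)
    pairs = _ranked_pairs(cmap.C, [(i, j) for i in range(L) for j in range(i + 1, L)])
    pairs = pairs[:n_top_pairs]
    Wc = center_blocks(W_linear.W)
    Jc = center_blocks(J_arr)
    w = np.concatenate([Wc[i, :, j, :].ravel() for i, j in pairs])
    j_ = np.concatenate([Jc[i, :, j, :].ravel() for i, j in pairs])
    sd = w.std()
    rho = np.full(len(cutoffs), np.nan)
    n_ret = np.zeros(len(cutoffs), dtype=np.int64)
    for k, b in enumerate(cutoffs):
        keep = np.abs(w) > b * sd
        n_ret[k] = int(keep.sum())
        if n_ret[k] < 3:
            warnings.warn(
                f"cutoff b={b}: fewer than 3 retained entries, rho undefined",
                stacklevel=2,
            )
            continue
        rho[k] = spearmanr(w[keep], j_[keep]).statistic
    return CouplingComparison(np.asarray(cutoffs), rho, n_ret)


def comparison_to_tsv(comparison: CouplingComparison, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("b\trho\tn_retained\n")
        for b, r, n in zip(comparison.cutoffs, comparison.rho, comparison.n_retained):
            fh.write(f"{b:g}\t{r:.6g}\t{n}\n")
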