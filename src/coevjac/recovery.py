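"""Masked contact-recovery experiments.

The experiment probes how much sequence context a contact model needs: mask
the whole protein except two 11-residue segments, then progressively unmask
residues — symmetrically on the segments' outer flanks, at random, or at
random while avoiding the segments' neighbourhood — and track how the
predicted inter-segment contact block recovers relative to the fully
unmasked prediction,

    Recovery = sum_ij a_ij * b_ij / sum_ij a_ij^2,

over the 11x11 inter-segment block (a: full-context probabilities, b:
masked-context).  Recovery above 0.5 (strict) counts as recovered.  A one-
step recovery increase above 0.5 is a "jump" — step-function motif
completion — subject to a stability filter on the following 10 steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import MASK_INDEX
from .couplings import ContactMap
from .models import ContactModel, ModelContractError

__all__ = [
    "SegmentPair",
    "MaskPattern",
    "RecoveryCurve",
    "JumpReport",
    "select_segment_pairs",
    "build_mask_schedule",
    "contact_recovery",
    "run_recovery_experiment",
    "detect_jump",
    "min_unmasked_asymmetric",
]

SEGMENT_LENGTH = 11
HALF = SEGMENT_LENGTH // 2
BLOCK_SCORE_THRESHOLD = 10.0
RECOVERY_THRESHOLD = 0.5
JUMP_CUTOFF = 0.5


@dataclass(frozen=True)
class SegmentPair:
    """Two non-overlapping 11-residue segments centred at (center1, center2)."""

    center1: int
    center2: int
    length: int = SEGMENT_LENGTH
    separation_class: str = "near-15"
    block_score: float = 0.0

    def __post_init__(self) -> None:
        if self.center1 >= self.center2:
            raise ValueError("center1 must precede center2")
        half = self.length // 2
        if self.center2 - self.center1 < self.length:
            raise ValueError("segments overlap")
        if self.center1 - half < 0:
            raise ValueError("first segment extends past the N terminus")

    @property
    def start1(self) -> int:
        return self.center1 - self.length // 2

    @property
    def end1(self) -> int:  # inclusive
        return self.center1 + self.length // 2

    @property
    def start2(self) -> int:
        return self.center2 - self.length // 2

    @property
    def end2(self) -> int:  # inclusive
        return self.center2 + self.length // 2

    def block(self, M: np.ndarray) -> np.ndarray:
        """The 11x11 inter-segment block of a full L x L map."""
        return M[self.start1 : self.end1 + 1, self.start2 : self.end2 + 1]


@dataclass
class MaskPattern:
    """Which positions a model gets to see at one schedule step."""

    unmasked: np.ndarray
    step: int = 0
    truncated: bool = False

    def __post_init__(self) -> None:
        self.unmasked = np.asarray(self.unmasked, dtype=bool)

    @property
    def n_unmasked(self) -> int:
        return int(self.unmasked.sum())

    def apply(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens, dtype=np.int64)
        return np.where(self.unmasked, tokens, MASK_INDEX)


@dataclass
class RecoveryCurve:
    """Recovery per schedule step, with the unmasked count at each step."""

    steps: list
    values: np.ndarray
    n_unmasked: np.ndarray
    strategy: str = "flank-symmetric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.n_unmasked = np.asarray(self.n_unmasked, dtype=np.int64)
        if not (len(self.steps) == self.values.size == self.n_unmasked.size):
            raise ValueError("steps, values and n_unmasked must align")


@dataclass
class JumpReport:
    """Step-change classification of a recovery curve."""

    reached_recovery: bool
    max_one_step_increase: float = 0.0
    is_jump: bool = False
    jump_step: int | None = None
    stable_after: bool | None = None
    total_unmasked_at_jump: int | None = None


def _segment_block_sum(C: np.ndarray, s1: int, s2: int) -> float:
    return float(C[s1 : s1 + SEGMENT_LENGTH, s2 : s2 + SEGMENT_LENGTH].sum())


def _pair_distance(p: SegmentPair, q: SegmentPair) -> float:
    return float(np.hypot(p.center1 - q.center1, p.center2 - q.center2))


def select_segment_pairs(
    base_map: ContactMap,
    mode: str = "near-15",
    sse_centers: list[int] | None = None,
    max_per_protein: int = 3,
    seed: int = 0,
    block_threshold: float = BLOCK_SCORE_THRESHOLD,
) -> list[SegmentPair]:
    """Select interacting 11-aa segment pairs from a contact-probability map.

    ``near-15``: scan all center pairs separated by exactly 15 residues.
    ``mid-50-100`` / ``far-gt100``: pairs of SSE centers (supplied, not
    computed) with separation in [50, 100] or > 100 and segments more than 10
    residues from the termini.  A pair qualifies when its 11x11 block sum
    strictly exceeds ``block_threshold``.  Up to ``max_per_protein`` pairs
    are sampled: the first uniformly at random, the rest by repeatedly taking
    the candidate farthest (max-min center distance) from those selected.
    """
    C = base_map.C
    L = base_map.L
    candidates: list[SegmentPair] = []
    if mode == "near-15":
        for c1 in range(HALF, L - HALF):
            c2 = c1 + 15
            if c2 + HALF >= L:
                break
            score = _segment_block_sum(C, c1 - HALF, c2 - HALF)
            if score > block_threshold:
                candidates.append(SegmentPair(c1, c2, separation_class=mode, block_score=score))
    elif mode in {"mid-50-100", "far-gt100"}:
        if sse_centers is None:
            raise ValueError(f"mode {mode!r} requires sse_centers")
        centers = sorted(set(int(c) for c in sse_centers))
        for a_idx in range(len(centers)):
            for b_idx in range(a_idx + 1, len(centers)):
                c1, c2 = centers[a_idx], centers[b_idx]
                sep = c2 - c1
                if mode == "mid-50-100" and not (50 <= sep <= 100):
                    continue
                if mode == "far-gt100" and sep <= 100:
                    continue
                # more than 10 residues between segment ends and the termini
                if c1 - HALF <= 10 or c2 + HALF >= L - 1 - 10:
                    continue
                score = _segment_block_sum(C, c1 - HALF, c2 - HALF)
                if score > block_threshold:
                    candidates.append(
                        SegmentPair(c1, c2, separation_class=mode, block_score=score)
                    )
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if not candidates:
        return []
    rng = np.random.default_rng(seed)
    selected = [candidates.pop(int(rng.integers(len(candidates))))]
    while candidates and len(selected) < max_per_protein:
        best = max(
            candidates,
            key=lambda p: (min(_pair_distance(p, s) for s in selected), -p.center1, -p.center2),
        )
        candidates.remove(best)
        selected.append(best)
    return selected


def _base_unmasked(pair: SegmentPair, L: int) -> np.ndarray:
    u = np.zeros(L, dtype=bool)
    u[pair.start1 : pair.end1 + 1] = True
    u[pair.start2 : pair.end2 + 1] = True
    return u


def build_mask_schedule(
    pair: SegmentPair,
    L: int,
    strategy: str = "flank-symmetric",
    steps=None,
    seed: int = 0,
) -> list[MaskPattern]:
    """Unmasking schedules for one segment pair.

    Strategies:

    * ``flank-symmetric`` — step k unmasks k residues on each *outer* flank
      (left of the first segment, right of the second); flanks hitting a
      terminus are truncated and flagged.
    * ``flank-asymmetric`` — steps are (k1, k2) tuples varying the two outer
      flanks independently.
    * ``random`` — step k unmasks 2k of the masked positions, nested so each
      pattern contains its predecessor.
    * ``random-avoid-30`` — as random, but never within 30 residues of any
      segment end.

    Both segments stay unmasked in every pattern.
    """
    if steps is None:
        steps = list(range(0, 11))
    base = _base_unmasked(pair, L)
    patterns: list[MaskPattern] = []
    if strategy in {"flank-symmetric", "flank-asymmetric"}:
        for step in steps:
            k1, k2 = (step, step) if strategy == "flank-symmetric" else step
            u = base.copy()
            lo = pair.start1 - k1
            hi = pair.end2 + k2
            truncated = lo < 0 or hi > L - 1
            u[max(lo, 0) : pair.start1] = True
            u[pair.end2 + 1 : min(hi, L - 1) + 1] = True
            patterns.append(MaskPattern(u, step=step, truncated=truncated))
        return patterns
    if strategy in {"random", "random-avoid-30"}:
        eligible = ~base
        if strategy == "random-avoid-30":
            ends = [pair.start1, pair.end1, pair.start2, pair.end2]
            pos = np.arange(L)
            near = np.zeros(L, dtype=bool)
            for e in ends:
                near |= np.abs(pos - e) <= 30
            eligible &= ~near
        order = np.random.default_rng(seed).permutation(np.nonzero(eligible)[0])
        for step in steps:
            n = min(2 * step, order.size)
            u = base.copy()
            u[order[:n]] = True
            patterns.append(MaskPattern(u, step=step, truncated=n < 2 * step))
        return patterns
    raise ValueError(f"unknown strategy: {strategy!r}")


def contact_recovery(reference_block: np.ndarray, masked_block: np.ndarray) -> float:
    """Recovery statistic sum(a*b) / sum(a^2) over matched blocks.

    Returns NaN with a warning when the reference block is all zero.
    """
    a = np.asarray(reference_block, dtype=np.float64)
    b = np.asarray(masked_block, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("blocks must have identical shape")
    denom = float((a * a).sum())
    if denom == 0.0:
        warnings.warn("reference block is all zero; recovery undefined", stacklevel=2)
        return float("nan")
    return float((a * b).sum() / denom)


def run_recovery_experiment(
    model: ContactModel,
    sequence: np.ndarray,
    pair: SegmentPair,
    strategy: str = "flank-symmetric",
    steps=None,
    seed: int = 0,
) -> RecoveryCurve:
    """Recovery of the inter-segment block across an unmasking schedule.

    The reference block ``a`` comes from the model's fully unmasked output;
    each schedule step contributes ``b`` from the masked prediction.
    """
    tokens = np.asarray(sequence, dtype=np.int64)
    L = tokens.size
    full = np.asarray(model.contacts(tokens), dtype=np.float64)
    if full.shape != (L, L):
        raise ModelContractError(f"contact model returned {full.shape}, expected ({L}, {L})")
    a = pair.block(full)
    patterns = build_mask_schedule(pair, L, strategy=strategy, steps=steps, seed=seed)
    values, counts = [], []
    for pat in patterns:
        out = np.asarray(model.contacts(pat.apply(tokens)), dtype=np.float64)
        if out.shape != (L, L):
            raise ModelContractError(
                f"contact model returned {out.shape}, expected ({L}, {L})"
            )
        values.append(contact_recovery(a, pair.block(out)))
        counts.append(pat.n_unmasked)
    return RecoveryCurve([p.step for p in patterns], np.array(values), np.array(counts), strategy)


def detect_jump(curve: RecoveryCurve) -> JumpReport:
    """Classify step-function behaviour of a unit-increment flank curve.

    Curves never exceeding the 0.5 recovery threshold are reported as not
    recovered.  Otherwise the maximal one-step increase defines the jump
    (cutoff 0.5, strict); stability requires that fewer than 3 of the next
    10 steps drop more than 0.2 below the value at the jump.
    """
    v = curve.values
    if v.size == 0 or np.nanmax(v) <= RECOVERY_THRESHOLD:
        return JumpReport(reached_recovery=False)
    if v.size < 2:
        return JumpReport(reached_recovery=True, max_one_step_increase=0.0)
    diffs = np.diff(v)
    idx = int(np.nanargmax(diffs))
    max_inc = float(diffs[idx])
    is_jump = max_inc > JUMP_CUTOFF
    if not is_jump:
        return JumpReport(reached_recovery=True, max_one_step_increase=max_inc)
    v_jump = v[idx + 1]
    after = v[idx + 2 : idx + 12]
    n_drops = int((after < v_jump - 0.2).sum())
    return JumpReport(
        reached_recovery=True,
        max_one_step_increase=max_inc,
        is_jump=True,
        jump_step=curve.steps[idx + 1],
        stable_after=n_drops < 3,
        total_unmasked_at_jump=int(curve.n_unmasked[idx + 1]),
    )


def min_unmasked_asymmetric(
    model: ContactModel,
    sequence: np.ndarray,
    pair: SegmentPair,
    max_flank: int,
    threshold: float = RECOVERY_THRESHOLD,
) -> int | None:
    """Minimal total unmasked residues achieving recovery, over the (k1, k2)
    grid of independently varied outer flanks.  None if never achieved."""
    tokens = np.asarray(sequence, dtype=np.int64)
    L = tokens.size
    a = pair.block(np.asarray(model.contacts(tokens), dtype=np.float64))
    best: int | None = None
    for total in range(0, 2 * max_flank + 1):
        for k1 in range(0, min(total, max_flank) + 1):
            k2 = total - k1
            if k2 > max_flank:
                continue
            pat = build_mask_schedule(pair, L, "flank-asymmetric", [(k1, k2)])[0]
            out = np.asarray(model.contacts(pat.apply(tokens)), dtype=np.float64)
            if contact_recovery(a, pair.block(out)) > threshold:
                return pat.n_unmasked
    return best
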