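"""Segment-pair selection, unmasking schedules, recovery and jump detection."""

import numpy as np
import pytest

from coevjac import (
    ContactMap,
    MASK_INDEX,
    RecoveryCurve,
    SegmentPair,
    SyntheticContactModel,
    build_mask_schedule,
    contact_recovery,
    detect_jump,
    min_unmasked_asymmetric,
    run_recovery_experiment,
    select_segment_pairs,
)


def _map_with_block(L, c1, c2, value=0.5):
    C = np.zeros((L, L))
    C[c1 - 5 : c1 + 6, c2 - 5 : c2 + 6] = value
    return np.maximum(C, C.T)


class TestSelectSegmentPairs:
    def test_block_sum_threshold_is_strict(self):
        L = 60
        # 121 cells at v sums to 121 v: pick v so sums land at 10.5 and 9.8
        for total, expect in [(10.5, 1), (9.8, 0)]:
            C = _map_with_block(L, 20, 35, value=total / 121)
            pairs = select_segment_pairs(ContactMap(C), "near-15", seed=0)
            assert len(pairs) == expect

    def test_all_zero_map_gives_empty_list(self):
        pairs = select_segment_pairs(ContactMap(np.zeros((80, 80))), "near-15")
        assert pairs == []

    def test_farthest_point_sampling_rule(self):
        """With >3 qualifying candidates, the 2nd and 3rd picks must maximise
        the minimum center distance to already-selected pairs (brute force)."""
        L = 300
        C = np.zeros((L, L))
        centers = [(20, 35), (80, 95), (150, 165), (220, 235), (270, 285)]
        # 0.09 per cell: the aligned 121-cell block sums to 10.89 > 10, while
        # any off-by-one window overlaps at most 110 cells (9.9, rejected),
        # so exactly these five candidate pairs qualify
        for c1, c2 in centers:
            C[c1 - 5 : c1 + 6, c2 - 5 : c2 + 6] = 0.09
        C = np.maximum(C, C.T)
        got = select_segment_pairs(ContactMap(C), "near-15", max_per_protein=3, seed=1)
        assert len(got) == 3
        candidates = set(centers)
        selected = [(got[0].center1, got[0].center2)]
        assert selected[0] in candidates
        for step in (1, 2):
            remaining = candidates - set(selected)
            best = max(
                min(np.hypot(p[0] - s[0], p[1] - s[1]) for s in selected)
                for p in remaining
            )
            picked = (got[step].center1, got[step].center2)
            assert picked in remaining
            d = min(np.hypot(picked[0] - s[0], picked[1] - s[1]) for s in selected)
            assert d == pytest.approx(best)
            selected.append(picked)

    def test_sse_modes_respect_separation_and_termini(self):
        L = 260
        sse_centers = [12, 30, 90, 150, 252]
        C = np.ones((L, L)) * 0.2  # every block qualifies
        mid = select_segment_pairs(
            ContactMap(C), "mid-50-100", sse_centers=sse_centers, max_per_protein=10, seed=0
        )
        far = select_segment_pairs(
            ContactMap(C), "far-gt100", sse_centers=sse_centers, max_per_protein=10, seed=0
        )
        for p in mid:
            assert 50 <= p.center2 - p.center1 <= 100
            assert p.start1 > 10 and p.end2 < L - 1 - 10
        for p in far:
            assert p.center2 - p.center1 > 100
        # center 12 (segment start 7 <= 10) and 252 (too close to C terminus) excluded
        used = {c for p in mid + far for c in (p.center1, p.center2)}
        assert 12 not in used and 252 not in used

    def test_sse_mode_requires_centers(self):
        with pytest.raises(ValueError, match="sse_centers"):
            select_segment_pairs(ContactMap(np.zeros((200, 200))), "mid-50-100")


class TestBuildMaskSchedule:
    PAIR = SegmentPair(40, 120)

    def test_step_zero_unmasks_exactly_the_segments(self):
        pat = build_mask_schedule(self.PAIR, 200, "flank-symmetric", [0])[0]
        assert pat.n_unmasked == 22

    def test_flank_symmetric_grows_outer_flanks_only(self):
        pat = build_mask_schedule(self.PAIR, 200, "flank-symmetric", [3])[0]
        u = np.nonzero(pat.unmasked)[0]
        expected = set(range(32, 46)) | set(range(115, 129))
        assert set(u.tolist()) == expected

    def test_random_avoid_30_keeps_clear_of_segment_ends(self):
        pats = build_mask_schedule(self.PAIR, 300, "random-avoid-30", list(range(11)), seed=3)
        ends = [self.PAIR.start1, self.PAIR.end1, self.PAIR.start2, self.PAIR.end2]
        base = set(range(35, 46)) | set(range(115, 126))
        for pat in pats:
            for pos in np.nonzero(pat.unmasked)[0]:
                if pos in base:
                    continue
                assert min(abs(pos - e) for e in ends) > 30

    def test_matched_counts_across_strategies(self):
        for k in range(1, 11):
            counts = {
                strat: build_mask_schedule(self.PAIR, 300, strat, [k], seed=5)[0].n_unmasked
                for strat in ("flank-symmetric", "random", "random-avoid-30")
            }
            assert len(set(counts.values())) == 1  # all equal: 22 + 2k
            assert counts["flank-symmetric"] == 22 + 2 * k

    def test_random_schedules_are_nested(self):
        pats = build_mask_schedule(self.PAIR, 300, "random", list(range(11)), seed=7)
        for a, b in zip(pats, pats[1:]):
            assert (b.unmasked | a.unmasked == b.unmasked).all()

    def test_flank_truncation_flagged_at_boundary(self):
        pair = SegmentPair(6, 40)
        pat = build_mask_schedule(pair, 200, "flank-symmetric", [5])[0]
        assert pat.truncated
        assert pat.unmasked[:2].all() or pat.unmasked[0]

    def test_segments_always_unmasked(self):
        for strat in ("flank-symmetric", "random", "random-avoid-30"):
            for pat in build_mask_schedule(self.PAIR, 300, strat, list(range(6)), seed=1):
                assert pat.unmasked[35:46].all() and pat.unmasked[115:126].all()


class TestContactRecovery:
    def test_identical_blocks_give_one(self, rng):
        a = rng.random((11, 11))
        assert contact_recovery(a, a) == pytest.approx(1.0)

    def test_zero_masked_block_gives_zero(self, rng):
        a = rng.random((11, 11))
        assert contact_recovery(a, np.zeros_like(a)) == 0.0

    def test_half_signal_sits_exactly_on_threshold(self):
        a = np.full((11, 11), 0.6)
        value = contact_recovery(a, a / 2)
        assert value == pytest.approx(0.5)
        assert not value > 0.5  # strict rule: 0.5 is NOT recovered

    def test_zero_reference_is_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(contact_recovery(np.zeros((11, 11)), np.ones((11, 11))))

    def test_linear_in_masked_block(self, rng):
        a = rng.random((11, 11))
        b = rng.random((11, 11))
        r1 = contact_recovery(a, b)
        assert contact_recovery(a, 0.25 * b) == pytest.approx(0.25 * r1)


class TestRunRecoveryExperiment:
    def test_synthetic_step_function_and_round_trip(self):
        """The synthetic model's window rule predicts a 0 -> 1 step at flank
        length context_window - 10; the experiment must find exactly that."""
        L, w = 200, 14
        pair = SegmentPair(40, 160, separation_class="far-gt100")
        C = _map_with_block(L, 40, 160, 0.5)
        model = SyntheticContactModel(C, context_window=w)
        tokens = np.zeros(L, dtype=np.int64)
        curve = run_recovery_experiment(model, tokens, pair, steps=list(range(11)))
        expected_step = w - 10
        np.testing.assert_array_equal(
            curve.values, (np.arange(11) >= expected_step).astype(float)
        )
        report = detect_jump(curve)
        assert report.is_jump and report.jump_step == expected_step
        assert report.total_unmasked_at_jump == 22 + 2 * expected_step
        assert report.stable_after

    def test_flank_unmasking_beats_random_on_local_context_model(self):
        """Flank unmasking reaches recovery > 0.5 with no more unmasked
        residues than random unmasking needs on average (20 seeded runs)."""
        L, w = 300, 16
        pair = SegmentPair(60, 220, separation_class="far-gt100")
        C = _map_with_block(L, 60, 220, 0.5)
        model = SyntheticContactModel(C, context_window=w)
        tokens = np.zeros(L, dtype=np.int64)
        steps = list(range(0, 60))
        flank = run_recovery_experiment(model, tokens, pair, "flank-symmetric", steps)
        n_flank = flank.n_unmasked[np.argmax(flank.values > 0.5)]
        randoms = []
        for seed in range(20):
            rcv = run_recovery_experiment(model, tokens, pair, "random", steps, seed=seed)
            over = np.nonzero(rcv.values > 0.5)[0]
            randoms.append(rcv.n_unmasked[over[0]] if over.size else rcv.n_unmasked[-1])
        assert n_flank <= np.mean(randoms)

    def test_asymmetric_minimum_not_more_than_symmetric(self):
        L, w = 200, 14
        pair = SegmentPair(40, 160)
        C = _map_with_block(L, 40, 160, 0.5)
        model = SyntheticContactModel(C, context_window=w)
        tokens = np.zeros(L, dtype=np.int64)
        total = min_unmasked_asymmetric(model, tokens, pair, max_flank=10)
        assert total is not None
        assert total <= 22 + 2 * (w - 10)


class TestDetectJump:
    def _curve(self, values, flank0=0):
        values = np.asarray(values, dtype=float)
        steps = list(range(flank0, flank0 + values.size))
        n = 22 + 2 * np.asarray(steps)
        return RecoveryCurve(steps, values, n)

    def test_step_at_fourteen_matches_construction(self):
        # 0 recovery through flank 13, full recovery from 14 on
        values = [0.0] * 14 + [1.0] * 5
        report = detect_jump(self._curve(values))
        assert report.is_jump
        assert report.jump_step == 14
        assert report.max_one_step_increase == pytest.approx(1.0)

    def test_gradual_curve_is_not_a_jump(self):
        values = np.arange(0, 1.0001, 0.05)
        report = detect_jump(self._curve(values))
        assert report.reached_recovery and not report.is_jump
        assert report.max_one_step_increase == pytest.approx(0.05)

    def test_unstable_oscillation_fails_stability_filter(self):
        # jumps to 1.0 then 4 of the next 10 steps drop by 0.25
        values = [0.0, 0.0, 1.0, 0.75, 0.75, 0.75, 0.75, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        report = detect_jump(self._curve(values))
        assert report.is_jump and report.stable_after is False

    def test_three_drops_is_still_stable_boundary(self):
        # exactly 2 drops below (jump value - 0.2): fewer than 3 -> stable
        values = [0.0, 1.0, 0.75, 0.75, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        assert detect_jump(self._curve(values)).stable_after

    def test_never_recovered_reported_as_such(self):
        report = detect_jump(self._curve([0.0, 0.1, 0.2, 0.3]))
        assert not report.reached_recovery and not report.is_jump
        assert report.jump_step is None
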