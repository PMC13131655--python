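"""Interval engine vs per-base brute-force oracles."""

import numpy as np
import pytest

from notokit.intervals import (
    CoverageIndex,
    GenomeLayout,
    GenomicInterval,
    IntervalError,
    PlacementError,
    distance_to_chrom_end,
    distance_to_nearest,
    feature_fraction,
    merge_within,
    passes_reciprocal,
    reciprocal_overlap,
    resolve_overlaps_by_score,
    shuffle_intervals,
)
from notokit.io import RepeatHit

from conftest import bitmap_cover, random_intervals


def GI(chrom, s, e):
    return GenomicInterval(chrom, s, e)


class TestReciprocalOverlap:
    def test_identity(self):
        a = GI("c", 0, 100)
        assert reciprocal_overlap(a, a) == (1.0, 1.0)
        assert passes_reciprocal(a, a, 0.75)

    def test_half_overlap_fails_threshold(self):
        a, b = GI("c", 0, 100), GI("c", 50, 150)
        assert reciprocal_overlap(a, b) == (0.5, 0.5)
        assert not passes_reciprocal(a, b, 0.75)

    def test_threshold_inclusive(self):
        # exactly 75 of 100 bases shared both ways -> inclusive pass
        assert passes_reciprocal(GI("c", 0, 100), GI("c", 25, 125), 0.75)
        # 74 shared -> below threshold
        assert not passes_reciprocal(GI("c", 0, 100), GI("c", 26, 126), 0.75)

    def test_different_chromosomes(self):
        assert reciprocal_overlap(GI("c1", 0, 10), GI("c2", 0, 10)) == (0.0, 0.0)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(IntervalError):
            GenomicInterval("c", 10, 10)

    def test_matches_base_counting_oracle(self, rng):
        for _ in range(1000):
            a, b = random_intervals(rng, 2)
            if a.chrom != b.chrom:
                expected = 0
            else:
                expected = int(
                    np.sum(
                        bitmap_cover([a], a.chrom, 20_000)
                        & bitmap_cover([b], a.chrom, 20_000)
                    )
                )
            fa, fb = reciprocal_overlap(a, b)
            assert fa == expected / a.length
            assert fb == expected / b.length


class TestMergeWithin:
    def test_gap_just_inside_merges(self):
        merged = merge_within([GI("c", 0, 10), GI("c", 109, 120)], max_gap=100)
        assert [m.interval for m in merged] == [GI("c", 0, 120)]

    def test_gap_at_boundary_does_not_merge(self):
        merged = merge_within([GI("c", 0, 10), GI("c", 110, 120)], max_gap=100)
        assert len(merged) == 2

    def test_key_separation(self):
        merged = merge_within(
            [GI("c", 0, 10), GI("c", 20, 30)], max_gap=100, keys=["x", "y"]
        )
        assert len(merged) == 2

    def test_matches_naive_pairwise_oracle(self, rng):
        ivs = random_intervals(rng, 500, max_len=500)

        def naive(items, max_gap):
            items = [(iv.chrom, iv.start, iv.end) for iv in items]
            changed = True
            while changed:
                changed = False
                for i in range(len(items)):
                    for j in range(i + 1, len(items)):
                        ci, si, ei = items[i]
                        cj, sj, ej = items[j]
                        if ci != cj:
                            continue
                        gap = max(sj - ei, si - ej)
                        if gap < max_gap or gap < 0:
                            items[i] = (ci, min(si, sj), max(ei, ej))
                            items.pop(j)
                            changed = True
                            break
                    if changed:
                        break
            return sorted(items)

        for max_gap in (0, 5, 100):
            got = sorted(
                (m.interval.chrom, m.interval.start, m.interval.end)
                for m in merge_within(ivs, max_gap)
            )
            assert got == naive(ivs, max_gap)

    def test_idempotent(self, rng):
        ivs = random_intervals(rng, 200, max_len=400)
        once = [m.interval for m in merge_within(ivs, 50)]
        twice = [m.interval for m in merge_within(once, 50)]
        assert once == twice

    def test_members_cover_all_inputs(self, rng):
        ivs = random_intervals(rng, 100, max_len=400)
        merged = merge_within(ivs, 50)
        members = sorted(i for m in merged for i in m.members)
        assert members == list(range(len(ivs)))


def _hit(chrom, s, e, score, family="fam"):
    return RepeatHit(
        interval=GenomicInterval(chrom, s, e),
        family=family,
        class_label="LINE",
        divergence_pct=1.0,
        score=score,
    )


class TestResolveOverlapsByScore:
    def test_identical_intervals_keep_higher_score(self):
        hits = [_hit("c", 0, 100, 10), _hit("c", 0, 100, 5)]
        out = resolve_overlaps_by_score(hits)
        assert len(out) == 1 and out[0].score == 10

    def test_disjoint_unchanged(self):
        hits = [_hit("c", 0, 50, 3), _hit("c", 60, 90, 7)]
        out = resolve_overlaps_by_score(hits)
        assert [(h.interval.start, h.interval.end) for h in out] == [(0, 50), (60, 90)]

    def test_lower_score_truncated(self):
        hits = [_hit("c", 0, 100, 1), _hit("c", 40, 60, 9)]
        out = resolve_overlaps_by_score(hits)
        spans = [(h.interval.start, h.interval.end, h.score) for h in out]
        assert spans == [(0, 40, 1), (40, 60, 9), (60, 100, 1)]

    def test_per_base_winner_matches_argmax_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 25))
            hits = []
            for i in range(n):
                s = int(rng.integers(0, 900))
                e = s + int(rng.integers(1, 120))
                hits.append(_hit("c", s, e, float(rng.integers(1, 8))))
            out = resolve_overlaps_by_score(hits)
            # oracle: winner at each base = best (score, -start, -index)
            winner = np.full(1100, -1)
            best = np.full((1100, 3), -np.inf)
            for i, h in enumerate(hits):
                key = np.array([h.score, -h.interval.start, -i])
                for pos in range(h.interval.start, h.interval.end):
                    if tuple(key) > tuple(best[pos]):
                        best[pos] = key
                        winner[pos] = i
            got = np.full(1100, -1.0)
            for h in out:
                for pos in range(h.interval.start, h.interval.end):
                    assert got[pos] == -1.0, "output hits overlap"
                    got[pos] = h.score
            for pos in range(1100):
                if winner[pos] >= 0:
                    assert got[pos] == hits[winner[pos]].score
                else:
                    assert got[pos] == -1.0

    def test_input_order_invariance(self, rng):
        hits = [
            _hit("c", int(rng.integers(0, 500)), int(rng.integers(501, 900)), float(s))
            for s in rng.integers(1, 100, size=12)
        ]
        a = resolve_overlaps_by_score(hits)
        b = resolve_overlaps_by_score(list(reversed(hits)))
        assert [(h.interval.start, h.interval.end, h.score) for h in a] == [
            (h.interval.start, h.interval.end, h.score) for h in b
        ]


class TestFeatureFraction:
    def test_full_cover(self):
        assert feature_fraction(GI("c", 0, 100), [GI("c", 0, 100)]) == 1.0

    def test_empty_annotation(self):
        assert feature_fraction(GI("c", 0, 100), []) == 0.0

    def test_window_clipped_at_chromosome_end(self):
        layout = GenomeLayout({"c": 150})
        # clipped window [100, 150); covered 25 of 50
        assert feature_fraction(GI("c", 100, 200), [GI("c", 125, 160)], layout) == 0.5

    def test_window_outside_chromosome_errors(self):
        layout = GenomeLayout({"c": 150})
        with pytest.raises(IntervalError):
            feature_fraction(GI("c", 150, 200), [], layout)

    def test_matches_bitmap_oracle(self, rng):
        ann = random_intervals(rng, 200, max_len=300)
        idx = CoverageIndex(ann)
        for _ in range(300):
            (w,) = random_intervals(rng, 1, max_len=2_000)
            bits = bitmap_cover(ann, w.chrom, 20_000)
            expected = int(bits[w.start : w.end].sum()) / w.length
            assert feature_fraction(w, idx) == expected


class TestDistances:
    def test_chromosome_end_distance(self):
        layout = GenomeLayout({"c": 100})
        assert distance_to_chrom_end(GI("c", 10, 20), layout) == 10
        assert distance_to_chrom_end(GI("c", 85, 95), layout) == 5

    def test_overlapping_target_is_zero(self):
        assert distance_to_nearest(GI("c", 10, 20), [GI("c", 15, 30)]) == 0

    def test_no_targets_returns_none(self):
        assert distance_to_nearest(GI("c", 10, 20), [GI("d", 0, 5)]) is None

    def test_matches_exhaustive_oracle(self, rng):
        targets = random_intervals(rng, 50, max_len=200)
        for _ in range(200):
            (x,) = random_intervals(rng, 1, max_len=100)
            best = None
            for t in targets:
                if t.chrom != x.chrom:
                    continue
                if min(t.end, x.end) > max(t.start, x.start):
                    d = 0
                else:
                    d = max(t.start - x.end, x.start - t.end, 0)
                best = d if best is None else min(best, d)
            assert distance_to_nearest(x, targets) == best


class TestShuffleIntervals:
    def test_deterministic_for_fixed_seed(self, two_chrom_layout, rng):
        ivs = random_intervals(rng, 50, max_len=500)
        a = shuffle_intervals(ivs, two_chrom_layout, seed=7)
        b = shuffle_intervals(ivs, two_chrom_layout, seed=7)
        assert a == b
        c = shuffle_intervals(ivs, two_chrom_layout, seed=8)
        assert a != c

    def test_lengths_preserved(self, two_chrom_layout, rng):
        ivs = random_intervals(rng, 100, max_len=500)
        out = shuffle_intervals(ivs, two_chrom_layout, seed=1)
        assert [iv.length for iv in out] == [iv.length for iv in ivs]

    def test_gaps_never_intersected(self):
        layout = GenomeLayout({"c": 10_000}, gaps=(GI("c", 4_000, 6_000),))
        ivs = [GI("c", 0, 300)] * 200
        for iv in shuffle_intervals(ivs, layout, seed=3):
            assert iv.overlap_bp(GI("c", 4_000, 6_000)) == 0

    def test_per_chromosome_counts_binomial(self):
        layout = GenomeLayout({"a": 15_000, "b": 5_000})
        ivs = [GI("a", 0, 1)] * 10_000
        out = shuffle_intervals(ivs, layout, seed=42)
        n_a = sum(1 for iv in out if iv.chrom == "a")
        p = 15_000 / 20_000
        sd = np.sqrt(10_000 * p * (1 - p))
        assert abs(n_a - 10_000 * p) < 3 * sd

    def test_too_long_interval_raises(self):
        layout = GenomeLayout({"c": 50})
        with pytest.raises(PlacementError):
            shuffle_intervals([GI("c", 0, 100)], layout, seed=1)
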