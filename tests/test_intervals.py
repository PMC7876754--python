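"""Interval algebra: arithmetic examples, merge fixpoint behaviour, and
agreement with per-base set oracles."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, strategies as st

from enhancerstates.intervals import (
    GenomicInterval,
    IntervalSet,
    NoNeighborError,
    coverage_fraction,
    merge_by_fraction,
    nearest_point_distance,
    overlap_bp,
    overlap_fraction,
)

from conftest import base_set, iv, oracle_coverage_fraction, oracle_overlap_bp

intervals_st = st.builds(
    lambda chrom, start, width: GenomicInterval(chrom, start, start + width),
    chrom=st.sampled_from(["chr1", "chr2"]),
    start=st.integers(0, 9_000),
    width=st.integers(1, 1_000),
)


class TestOverlapBp:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (iv("chr1", 0, 100), iv("chr1", 50, 150), 50),
            (iv("chr1", 0, 100), iv("chr1", 100, 200), 0),  # half-open abutment
            (iv("chr1", 0, 100), iv("chr2", 0, 100), 0),  # different chromosomes
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_bp(a, b) == expected
        assert overlap_bp(b, a) == expected

    @given(a=intervals_st, b=intervals_st)
    def test_matches_per_base_oracle_and_is_symmetric(self, a, b):
        ov = overlap_bp(a, b)
        assert ov == oracle_overlap_bp(a, b)
        assert ov == overlap_bp(b, a)
        assert ov <= min(a.width, b.width)


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "a, b, denom, expected",
        [
            (iv("chr1", 0, 100), iv("chr1", 50, 150), "of_a", 0.5),
            (iv("chr1", 0, 100), iv("chr1", 0, 100), "of_smaller", 1.0),
            (iv("chr1", 0, 1000), iv("chr1", 900, 950), "of_b", 1.0),  # contained
        ],
    )
    def test_examples(self, a, b, denom, expected):
        assert overlap_fraction(a, b, denom) == pytest.approx(expected)

    @given(a=intervals_st, b=intervals_st,
           denom=st.sampled_from(["of_a", "of_b", "of_smaller"]))
    def test_fraction_in_unit_interval(self, a, b, denom):
        assert 0.0 <= overlap_fraction(a, b, denom) <= 1.0

    def test_denominator_is_mandatory(self):
        with pytest.raises(TypeError):
            overlap_fraction(iv("chr1", 0, 10), iv("chr1", 0, 10))  # type: ignore[call-arg]


def _no_qualifying_pair(result: IntervalSet, min_frac: float) -> bool:
    items = list(result)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ov = overlap_bp(items[i], items[j])
            if ov and ov >= min_frac * min(items[i].width, items[j].width):
                return False
    return True


class TestMergeByFraction:
    def test_qualifying_pair_merges_to_union_span(self):
        result = merge_by_fraction(
            IntervalSet([iv("chr1", 0, 100), iv("chr1", 60, 160)]), 0.25
        )
        assert list(result) == [iv("chr1", 0, 160)]

    def test_subthreshold_overlap_left_unmerged(self):
        s = IntervalSet([iv("chr1", 0, 100), iv("chr1", 80, 200)])
        assert merge_by_fraction(s, 0.25) == s  # 20 bp is 0.20 / ~0.167

    def test_singleton_is_fixpoint(self):
        s = IntervalSet([iv("chr1", 0, 100)])
        assert merge_by_fraction(s, 0.5) == s

    def test_duplicates_collapse(self):
        result = merge_by_fraction(
            IntervalSet([iv("chr1", 5, 50), iv("chr1", 5, 50)]), 0.25
        )
        assert len(result) == 1

    def test_invalid_min_frac_rejected(self):
        with pytest.raises(ValueError):
            merge_by_fraction(IntervalSet([iv("chr1", 0, 10)]), 0.0)

    def test_chain_merging_reaches_fixpoint(self):
        # each neighbour pair overlaps 50% → everything collapses
        chain = IntervalSet([iv("chr1", i * 50, i * 50 + 100) for i in range(10)])
        result = merge_by_fraction(chain, 0.25)
        assert list(result) == [iv("chr1", 0, 550)]

    @given(
        st.lists(intervals_st, min_size=1, max_size=30),
        st.sampled_from([0.25, 0.5, 1.0]),
    )
    def test_merge_guarantees(self, items, min_frac):
        source = IntervalSet(items)
        result = merge_by_fraction(source, min_frac)
        # covered bases preserved: merging unions only overlapping pairs
        src_bases = set().union(*(base_set(x) for x in items))
        out_bases = set().union(*(base_set(x) for x in result))
        assert src_bases == out_bases
        # fixpoint: no output pair still qualifies
        assert _no_qualifying_pair(result, min_frac)
        # every input interval is contained in an output interval (never split);
        # a small interval nested in two non-merging outputs has two containers
        for x in items:
            containers = [
                y for y in result
                if y.chrom == x.chrom and y.start <= x.start and x.end <= y.end
            ]
            assert len(containers) >= 1
        # idempotent
        assert merge_by_fraction(result, min_frac) == result

    @given(st.lists(intervals_st, min_size=2, max_size=25), st.integers(0, 2**31 - 1))
    def test_input_order_independence(self, items, seed):
        shuffled = items[:]
        random.Random(seed).shuffle(shuffled)
        assert merge_by_fraction(IntervalSet(items), 0.25) == merge_by_fraction(
            IntervalSet(shuffled), 0.25
        )


class TestCoverageFraction:
    @pytest.mark.parametrize(
        "region, blocks, expected",
        [
            (iv("chr1", 0, 1000), [iv("chr1", 0, 400), iv("chr1", 500, 900)], 0.8),
            (iv("chr1", 0, 1000), [], 0.0),
            # overlapping blocks counted once
            (iv("chr1", 0, 1000), [iv("chr1", 0, 600), iv("chr1", 400, 1000)], 1.0),
        ],
    )
    def test_examples(self, region, blocks, expected):
        assert coverage_fraction(region, IntervalSet(blocks)) == pytest.approx(expected)

    @given(region=intervals_st, blocks=st.lists(intervals_st, max_size=10))
    def test_matches_per_base_oracle(self, region, blocks):
        got = coverage_fraction(region, IntervalSet(blocks))
        assert got == pytest.approx(oracle_coverage_fraction(region, blocks))
        assert 0.0 <= got <= 1.0

    @given(region=intervals_st, block=intervals_st, cut=st.integers(1, 999))
    def test_invariant_under_block_splitting(self, region, block, cut):
        if block.width < 2:
            return
        split_at = block.start + 1 + cut % (block.width - 1)
        whole = IntervalSet([block])
        halves = IntervalSet(
            [
                GenomicInterval(block.chrom, block.start, split_at),
                GenomicInterval(block.chrom, split_at, block.end),
            ]
        )
        assert coverage_fraction(region, whole) == pytest.approx(
            coverage_fraction(region, halves)
        )


class TestNearestPointDistance:
    def test_midpoint_to_single_point(self):
        point, dist = nearest_point_distance(iv("chr1", 69_500, 70_500), [("chr1", 10_000)])
        assert point == ("chr1", 10_000)
        assert dist == 60_000

    def test_point_at_midpoint_gives_zero(self):
        _, dist = nearest_point_distance(iv("chr1", 100, 200), [("chr1", 150)])
        assert dist == 0

    def test_no_point_on_chromosome_raises(self):
        with pytest.raises(NoNeighborError):
            nearest_point_distance(iv("chr1", 0, 100), [("chr2", 50)])

    def test_tie_breaks_to_lower_position(self):
        point, dist = nearest_point_distance(
            iv("chr1", 90, 110), [("chr1", 150), ("chr1", 50)]
        )
        assert point == ("chr1", 50)
        assert dist == 50


class TestGenomicInterval:
    @pytest.mark.parametrize("start, end", [(10, 10), (10, 5), (-1, 5)])
    def test_degenerate_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)
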