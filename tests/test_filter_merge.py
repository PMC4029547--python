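"""Size filtering and reciprocal-overlap duplicate removal."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from svunify.filter_merge import (
    FilterSpec,
    MergeConfig,
    UnknownCallerError,
    default_filter_spec,
    default_precision_profile,
    filter_calls,
    merge_callsets,
    mutual_overlap_exceeds,
    precision_of,
)
from svunify.model import PrecisionProfile

from .conftest import make_call
from .oracles import brute_merge


def default_merge_config(**kw) -> MergeConfig:
    return MergeConfig(precision_profile=default_precision_profile(), **kw)


class TestFilter:
    def test_keeps_calls_inside_their_callers_trusted_range(self):
        spec = default_filter_spec()
        kept = filter_calls([make_call("c1", 0, 80, "HC")], spec)
        assert len(kept) == 1

    def test_drops_out_of_range_and_preserves_order(self):
        spec = default_filter_spec()
        calls = [
            make_call("c1", 0, 5_000, "HC"),  # 5 kb is far outside HC's 1-100 bp
            make_call("c1", 0, 50, "HC"),
            make_call("c2", 0, 2_000, "BD"),
            make_call("c2", 0, 500, "BD"),  # below BD's 1 kb floor
        ]
        kept = filter_calls(calls, spec)
        assert kept == [calls[1], calls[2]]

    def test_range_bounds_are_inclusive(self):
        spec = FilterSpec(ranges={"HC": (10, 100)})
        sizes = [9, 10, 100, 101]
        kept = filter_calls([make_call("c1", 0, s, "HC") for s in sizes], spec)
        assert [c.size for c in kept] == [10, 100]

    def test_empty_input(self):
        assert filter_calls([], default_filter_spec()) == []

    def test_unknown_caller_raises_unless_allowed(self):
        call = make_call("c1", 0, 50, "Delly")
        with pytest.raises(UnknownCallerError, match="Delly"):
            filter_calls([call], default_filter_spec())
        spec = FilterSpec(ranges=dict(default_filter_spec().ranges), allow_unlisted=True)
        assert filter_calls([call], spec) == [call]


class TestOverlapPredicate:
    def test_full_overlap(self):
        a = make_call("c1", 0, 300)
        assert mutual_overlap_exceeds(a, a, 2 / 3)

    def test_exactly_two_thirds_is_not_more_than(self):
        a, b = make_call("c1", 0, 300), make_call("c1", 100, 400, "BD")
        assert not mutual_overlap_exceeds(a, b, 2 / 3)  # overlap 200 == 2/3 * 300

    def test_strictly_above_two_thirds(self):
        a, b = make_call("c1", 0, 300), make_call("c1", 90, 390, "BD")
        assert mutual_overlap_exceeds(a, b, 2 / 3)  # overlap 210 > 200

    def test_reciprocal_vs_either_mode(self):
        small, big = make_call("c1", 0, 100), make_call("c1", 0, 1_000, "BD")
        assert not mutual_overlap_exceeds(small, big, 2 / 3, reciprocal=True)
        assert mutual_overlap_exceeds(small, big, 2 / 3, reciprocal=False)

    def test_disjoint_and_cross_contig(self):
        a = make_call("c1", 0, 300)
        assert not mutual_overlap_exceeds(a, make_call("c1", 300, 600), 2 / 3)
        assert not mutual_overlap_exceeds(a, make_call("c2", 0, 300), 2 / 3)


class TestPrecisionLookup:
    def test_configured_value(self):
        profile = PrecisionProfile.from_rows([("HC", 1, 101, 0.95)])
        assert precision_of(make_call("c1", 0, 50, "HC"), profile) == 0.95

    def test_bin_edge_belongs_to_containing_half_open_bin(self):
        profile = PrecisionProfile.from_rows([("HC", 1, 100, 0.9), ("HC", 100, 1000, 0.4)])
        assert precision_of(make_call("c1", 0, 100, "HC"), profile) == 0.4

    def test_unknown_caller_gets_default(self):
        profile = PrecisionProfile.from_rows([("HC", 1, 101, 0.95)], default=0.0)
        assert precision_of(make_call("c1", 0, 50, "Delly"), profile) == 0.0


class TestMerge:
    def test_identical_span_keeps_higher_precision_caller(self):
        pindel = make_call("c1", 10_000, 15_000, "Pindel")
        bd = make_call("c1", 10_000, 15_000, "BD")
        merged = merge_callsets([[pindel], [bd]], default_merge_config())
        assert merged == [pindel]  # Pindel prior 0.95 > BD 0.93 at 5 kb

    def test_sub_threshold_overlap_keeps_both(self):
        a = make_call("c1", 0, 300, "Pindel")
        b = make_call("c1", 100, 400, "BD")  # overlap exactly 2/3 of each: not a duplicate
        assert merge_callsets([[a], [b]], default_merge_config()) == [a, b]

    def test_non_overlapping_callset_unchanged_up_to_sorting(self):
        calls = [make_call("c1", 1_000 * i, 1_000 * i + 200, "Pindel") for i in range(5)]
        merged = merge_callsets([calls[::-1]], default_merge_config())
        assert merged == calls

    def test_cross_contig_calls_never_interact(self):
        a = make_call("c1", 0, 5_000, "Pindel")
        b = make_call("c2", 0, 5_000, "BD")
        assert len(merge_callsets([[a], [b]], default_merge_config())) == 2

    def test_precision_tie_broken_by_caller_priority(self):
        profile = PrecisionProfile.from_rows(
            [("HC", 1, 101, 0.9), ("Pindel", 1, 101, 0.9)]
        )
        cfg = MergeConfig(precision_profile=profile, caller_priority=("HC", "Pindel", "BD"))
        hc = make_call("c1", 0, 80, "HC")
        pindel = make_call("c1", 0, 80, "Pindel")
        assert merge_callsets([[pindel], [hc]], cfg) == [hc]

    def _random_callsets(self, rng, n_sets=3, n_calls=12):
        sets = []
        for _ in range(n_sets):
            calls = []
            for _ in range(n_calls):
                start = int(rng.integers(0, 3_000))
                size = int(rng.integers(50, 600))
                caller = str(rng.choice(["HC", "Pindel", "BD", "Delly"]))
                calls.append(make_call("c1", start, start + size, caller))
            sets.append(calls)
        return sets

    def _cfg_with_all_callers(self):
        profile = PrecisionProfile.from_rows(
            [
                ("HC", 1, 10_000, 0.97),
                ("Pindel", 1, 10_000, 0.95),
                ("BD", 1, 10_000, 0.93),
                ("Delly", 1, 10_000, 0.93),
            ]
        )
        return MergeConfig(precision_profile=profile)

    def test_output_has_no_duplicated_pair(self, rng):
        cfg = self._cfg_with_all_callers()
        for _ in range(20):
            merged = merge_callsets(self._random_callsets(rng), cfg)
            for a, b in itertools.combinations(merged, 2):
                assert not mutual_overlap_exceeds(a, b, cfg.overlap_fraction)

    def test_idempotent(self, rng):
        cfg = self._cfg_with_all_callers()
        for _ in range(10):
            merged = merge_callsets(self._random_callsets(rng), cfg)
            again = merge_callsets([merged, merged], cfg)
            assert again == merged

    def test_order_invariant(self, rng):
        cfg = self._cfg_with_all_callers()
        callsets = self._random_callsets(rng)
        reference = merge_callsets(callsets, cfg)
        for perm in itertools.permutations(callsets):
            shuffled = [list(cs)[::-1] for cs in perm]
            assert merge_callsets(shuffled, cfg) == reference

    def test_matches_fixed_point_oracle(self, rng):
        cfg = self._cfg_with_all_callers()
        lookup = lambda c: precision_of(c, cfg.precision_profile)
        for _ in range(25):
            callsets = self._random_callsets(rng)
            merged = merge_callsets(callsets, cfg)
            expected = brute_merge(
                [c for cs in callsets for c in cs],
                cfg.overlap_fraction,
                lookup,
                cfg.caller_priority,
            )
            assert merged == expected
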