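"""Margin-extended quality metric and size-stratified precision/recall."""

from __future__ import annotations

from fractions import Fraction

import math
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svunify.evaluation import (
    EvaluationConfig,
    effective_region,
    evaluate,
    f_measure,
    precision_by_size,
    quality,
    recall_by_size,
)
from svunify.model import GenomicInterval, SizeBin, make_bins

from .conftest import make_call, make_del, random_instance
from .oracles import brute_precision_recall, brute_quality


@pytest.mark.parametrize(
    "interval,margin,contig_length,expected",
    [
        (("c1", 100, 101), 50, None, ("c1", 50, 151)),
        (("c1", 100, 200), 0, None, ("c1", 100, 200)),
        (("c1", 10, 20), 50, 40, ("c1", 0, 40)),
    ],
)
def test_effective_region(interval, margin, contig_length, expected):
    got = effective_region(GenomicInterval(*interval), margin, contig_length)
    assert (got.contig, got.start, got.end) == expected


def test_quality_of_one_bp_deletion_offset_ten_bp():
    """A 1-bp call 10 bp off a 1-bp truth scores 91/111 with the 50 bp margin."""
    call = make_call("c1", 110, 111)
    truth = make_del("c1", 100, 101)
    q = quality(call, truth, margin=50)
    assert q == pytest.approx(float(Fraction(91, 111)), abs=0)
    assert round(q, 1) == 0.8
    assert q == brute_quality(call.interval, truth.interval, 50)


def test_quality_identity_and_disjoint():
    call = make_call("c1", 500, 700)
    assert quality(call, make_del("c1", 500, 700), margin=50) == 1.0
    assert quality(call, make_del("c1", 500, 700), margin=0) == 1.0
    # separated by more than twice the margin: effective regions disjoint
    assert quality(make_call("c1", 0, 10), make_del("c1", 111, 120), margin=50) == 0.0
    assert quality(make_call("c1", 0, 10), make_del("c2", 0, 10), margin=50) == 0.0


def test_quality_rejects_insertion_truths():
    from svunify.model import TruthRecord

    ins = TruthRecord(
        interval=GenomicInterval("c1", 5, 6), sv_type="INS", inserted_sequence="ACGT"
    )
    with pytest.raises(ValueError):
        quality(make_call("c1", 0, 10), ins, margin=50)


@given(
    # keep starts >= max margin so the clamp at position 0 never engages
    # (translation invariance holds away from the contig edge)
    start_a=st.integers(100, 5_000),
    start_b=st.integers(100, 5_000),
    size_a=st.integers(1, 500),
    size_b=st.integers(1, 500),
    margin=st.integers(0, 100),
    shift=st.integers(0, 3_000),
)
def test_quality_symmetric_translation_invariant_and_bounded(
    start_a, start_b, size_a, size_b, margin, shift
):
    call = make_call("c1", start_a, start_a + size_a)
    truth = make_del("c1", start_b, start_b + size_b)
    q = quality(call, truth, margin)
    assert 0.0 <= q <= 1.0
    assert q == brute_quality(call.interval, truth.interval, margin)
    # symmetry: swap the roles of the two regions
    q_swapped = quality(
        make_call("c1", start_b, start_b + size_b), make_del("c1", start_a, start_a + size_a), margin
    )
    assert q == pytest.approx(q_swapped)
    # translation invariance
    q_shifted = quality(
        make_call("c1", start_a + shift, start_a + shift + size_a),
        make_del("c1", start_b + shift, start_b + shift + size_b),
        margin,
    )
    assert q == pytest.approx(q_shifted)


def test_margin_influence_vanishes_for_large_deletions():
    """At fixed offset, q grows monotonically with size and the 50-vs-0 bp
    margin difference converges to zero."""
    offset = 10
    previous = 0.0
    for size in (10, 100, 1_000, 10_000, 100_000):
        call = make_call("c1", 1_000 + offset, 1_000 + offset + size)
        truth = make_del("c1", 1_000, 1_000 + size)
        q = quality(call, truth, margin=50)
        assert q >= previous
        previous = q
    big_call = make_call("c1", 1_000, 1_000 + 100_000)
    big_truth = make_del("c1", 1_000, 1_000 + 100_000)
    assert abs(quality(big_call, big_truth, 50) - quality(big_call, big_truth, 0)) < 0.01


def test_precision_mixed_qualities_average():
    """Three calls in one bin with best qualities {1.0, 0.5, 0.0} average 0.5."""
    cfg = EvaluationConfig(margin=0, bins=make_bins((1, 100, 1_000)))
    truths = [make_del("c1", 0, 100)]
    calls = [
        make_call("c1", 0, 100),  # exact: q = 1
        make_call("c1", 0, 200),  # half-overlap: q = 100/200
        make_call("c1", 5_000, 5_100),  # no truth nearby: q = 0
    ]
    report = precision_by_size(calls, truths, cfg)
    row = report.row(SizeBin(100, 1_000))
    assert row.n_called == 3
    assert row.precision == pytest.approx(0.5)
    # one truth may be the maximizer of several calls: both overlapping calls used it
    bin_small = report.row(SizeBin(1, 100))
    assert bin_small.n_called == 0 and bin_small.precision is None


def test_recall_single_truth_partial_match():
    cfg = EvaluationConfig(margin=50, bins=make_bins((1, 10, 100)))
    truths = [make_del("c1", 100, 101)]
    calls = [make_call("c1", 110, 111)]
    report = recall_by_size(calls, truths, cfg)
    assert report.row(SizeBin(1, 10)).recall == pytest.approx(91 / 111)


def test_recall_zero_without_calls_and_ins_excluded():
    from svunify.model import TruthRecord

    cfg = EvaluationConfig(margin=50, bins=make_bins((1, 10, 100)))
    truths = [
        make_del("c1", 100, 105),
        TruthRecord(
            interval=GenomicInterval("c1", 500, 501), sv_type="INS", inserted_sequence="ACGTA"
        ),
    ]
    report = recall_by_size([], truths, cfg)
    row = report.row(SizeBin(1, 10))
    assert row.n_prepared == 1  # the INS record is not counted
    assert row.recall == 0.0


def test_perfect_calls_give_unit_precision_and_recall(rng):
    calls, truths = random_instance(rng, 0, 30)
    mirrored = [make_call(t.interval.contig, t.interval.start, t.interval.end) for t in truths]
    report = evaluate(mirrored, truths, EvaluationConfig())
    for row in report:
        if row.n_prepared:
            assert row.recall == pytest.approx(1.0)
        if row.n_called:
            assert row.precision == pytest.approx(1.0)
            assert row.f_measure == pytest.approx(1.0)


@pytest.mark.parametrize(
    "p,r,expected",
    [(1.0, 1.0, 1.0), (0.9, 0.9, 0.9), (1.0, 0.5, 2 / 3), (0.0, 0.0, 0.0)],
)
def test_f_measure(p, r, expected):
    assert f_measure(p, r) == pytest.approx(expected)


def test_precision_recall_match_all_pairs_oracle(rng):
    cfg = EvaluationConfig(margin=50, bins=make_bins((1, 10, 100, 1_000)))
    for _ in range(25):
        calls, truths = random_instance(
            rng, int(rng.integers(0, 30)), int(rng.integers(0, 30)), span=3_000, max_size=300
        )
        report = evaluate(calls, truths, cfg)
        oracle_p, oracle_r = brute_precision_recall(calls, truths, cfg.margin, cfg.bins)
        for row in report:
            assert (row.precision is None) == (row.bin not in oracle_p)
            assert (row.recall is None) == (row.bin not in oracle_r)
            if row.precision is not None:
                assert row.precision == pytest.approx(oracle_p[row.bin])
            if row.recall is not None:
                assert row.recall == pytest.approx(oracle_r[row.bin])


def test_report_tsv_round_trip(tmp_path, rng):
    import pandas as pd

    calls, truths = random_instance(rng, 20, 20)
    report = evaluate(calls, truths, EvaluationConfig())
    path = tmp_path / "report.tsv"
    report.write_tsv(path)
    frame = pd.read_csv(path, sep="\t")
    assert list(frame.columns) == [
        "bin_low", "bin_high", "n_called", "n_prepared", "precision", "recall", "f_measure",
    ]
    assert len(frame) == len(report.rows)
    for row, (_, loaded) in zip(report.rows, frame.iterrows()):
        assert loaded["n_called"] == row.n_called
        if row.precision is None:
            assert math.isnan(loaded["precision"])
        else:
            assert loaded["precision"] == pytest.approx(row.precision)
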