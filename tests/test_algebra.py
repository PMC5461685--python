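"""The interval implementation of every operator must match a per-base
dense-array oracle, and the expected set/algebra identities must hold."""

import numpy as np
import pytest

from conftest import GENOME_BP, dense, random_track
from sekit.algebra import (
    OPERATORS,
    SignalTrack,
    apply_pairwise,
    combine,
    normalize_operator,
    overlap_regions,
)
from sekit.errors import InputError, UsageError
from sekit.intervals import GenomicInterval, Peak, Read


def dense_op(op, a, b):
    """Independent per-base evaluation of one operator on dense arrays."""
    if op == "AND":
        return np.where((a > 0) & (b > 0), a, 0.0)
    if op == "OR":
        return np.where(a > 0, a, b)
    if op == "NOT":
        return np.where(b == 0, a, 0.0)
    if op == "XOR":
        return np.where((a > 0) & (b == 0), a, np.where((a == 0) & (b > 0), b, 0.0))
    if op == "+":
        return a + b
    if op == "-":
        return np.maximum(a - b, 0.0)
    if op == "SYM":
        return np.abs(a - b)
    raise AssertionError(op)


A = SignalTrack([("chr1", 100, 200, 5.0)])
B = SignalTrack([("chr1", 150, 250, 8.0)])


@pytest.mark.parametrize(
    "op,expected",
    [
        ("+", [(100, 150, 5.0), (150, 200, 13.0), (200, 250, 8.0)]),
        ("-", [(100, 150, 5.0)]),
        ("NOT", [(100, 150, 5.0)]),
        ("XOR", [(100, 150, 5.0), (200, 250, 8.0)]),
        ("SYM", [(100, 150, 5.0), (150, 200, 3.0), (200, 250, 8.0)]),
        ("AND", [(150, 200, 5.0)]),
        ("OR", [(100, 200, 5.0), (200, 250, 8.0)]),
    ],
)
def test_two_peak_worked_example(op, expected):
    assert apply_pairwise(op, A, B).segments("chr1") == expected


@pytest.mark.parametrize("op", OPERATORS)
def test_operator_matches_dense_oracle(op):
    rng = np.random.default_rng(7)
    for _ in range(60):
        a, b = random_track(rng), random_track(rng)
        got = dense(apply_pairwise(op, a, b))
        want = dense_op(op, dense(a), dense(b))
        np.testing.assert_allclose(got, want)


@pytest.mark.parametrize("op", OPERATORS)
def test_self_application_identities(op):
    rng = np.random.default_rng(11)
    for _ in range(20):
        a = random_track(rng)
        result = apply_pairwise(op, a, a)
        if op in ("AND", "OR"):
            assert result == a
        elif op in ("NOT", "XOR", "-", "SYM"):
            assert result.is_empty()


def test_plus_with_empty_is_identity():
    rng = np.random.default_rng(3)
    empty = SignalTrack()
    for _ in range(10):
        a = random_track(rng)
        assert apply_pairwise("+", a, empty) == a
        assert apply_pairwise("+", empty, a) == a


@pytest.mark.parametrize("op", ["+", "SYM"])
def test_arithmetic_commutativity(op):
    rng = np.random.default_rng(5)
    for _ in range(20):
        a, b = random_track(rng), random_track(rng)
        assert apply_pairwise(op, a, b) == apply_pairwise(op, b, a)


@pytest.mark.parametrize("op", ["AND", "OR", "XOR"])
def test_boolean_support_commutativity(op):
    rng = np.random.default_rng(9)
    for _ in range(20):
        a, b = random_track(rng), random_track(rng)
        s1 = apply_pairwise(op, a, b).support()
        s2 = apply_pairwise(op, b, a).support()
        assert s1 == s2


def test_support_algebra_against_set_oracle():
    rng = np.random.default_rng(13)
    for _ in range(30):
        a, b = random_track(rng), random_track(rng)
        sa = {i for i in range(GENOME_BP) if dense(a)[i] > 0}
        sb = {i for i in range(GENOME_BP) if dense(b)[i] > 0}
        for op, want in (
            ("AND", sa & sb),
            ("OR", sa | sb),
            ("NOT", sa - sb),
            ("XOR", sa ^ sb),
        ):
            got = set()
            for iv in apply_pairwise(op, a, b).support():
                got.update(range(iv.start, iv.end))
            assert got == want, op


def test_all_outputs_clamped_nonnegative_and_zero_free():
    rng = np.random.default_rng(17)
    for _ in range(20):
        a, b = random_track(rng), random_track(rng)
        for op in OPERATORS:
            for _, _, v in apply_pairwise(op, a, b).segments("chr1"):
                assert v > 0


class TestBuildTrack:
    def test_read_coverage(self):
        reads = [
            Read(GenomicInterval("chr1", 0, 100)),
            Read(GenomicInterval("chr1", 50, 150)),
        ]
        track = SignalTrack.from_reads(reads)
        assert track.segments("chr1") == [(0, 50, 1.0), (50, 100, 2.0), (100, 150, 1.0)]

    def test_empty_input(self):
        assert SignalTrack.from_reads([]).is_empty()

    def test_negative_bedgraph_rejected(self):
        with pytest.raises(InputError):
            SignalTrack([("chr1", 0, 10, -1.0)])

    def test_peak_track_height(self):
        track = SignalTrack.from_peaks([Peak(GenomicInterval("chr1", 10, 20), 4.0)])
        assert track.segments("chr1") == [(10, 20, 4.0)]


class TestSupport:
    def test_adjacent_segments_merge(self):
        t = SignalTrack([("chr1", 0, 50, 1.0), ("chr1", 50, 100, 2.0)])
        assert t.support() == [GenomicInterval("chr1", 0, 100)]

    def test_gap_splits_support(self):
        t = SignalTrack([("chr1", 0, 10, 1.0), ("chr1", 20, 30, 1.0)])
        assert len(t.support()) == 2

    def test_overlap_regions(self):
        assert overlap_regions(A, B) == [GenomicInterval("chr1", 150, 200)]
        far = SignalTrack([("chr1", 1000, 1100, 1.0)])
        assert overlap_regions(A, far) == []
        nested = SignalTrack([("chr1", 20, 30, 2.0)])
        wide = SignalTrack([("chr1", 0, 100, 1.0)])
        assert overlap_regions(wide, nested) == [GenomicInterval("chr1", 20, 30)]


class TestCombine:
    def test_single_signal_identity(self):
        assert combine([A], []) == A

    def test_left_fold_matches_dense_composition(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            a, b, c = random_track(rng), random_track(rng), random_track(rng)
            got = dense(combine([a, b, c], ["+", "NOT"]))
            want = dense_op("NOT", dense_op("+", dense(a), dense(b)), dense(c))
            np.testing.assert_allclose(got, want)

    def test_arity_mismatch(self):
        with pytest.raises(UsageError):
            combine([A, B], ["+", "NOT"])
        with pytest.raises(UsageError):
            combine([], [])

    def test_unknown_operator_token(self):
        with pytest.raises(UsageError):
            apply_pairwise("NAND", A, B)

    def test_token_aliases(self):
        assert normalize_operator("sub") == "-"
        assert normalize_operator("and") == "AND"
        assert normalize_operator("+") == "+"
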