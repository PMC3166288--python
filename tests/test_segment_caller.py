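"""Segment averaging, interval calling, and the per-residue profile."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nolscan.params import DEFAULT_PARAMETERS, Parameters
from nolscan.segment_caller import (
    CandidateSegmentProfile,
    NoLSInterval,
    WindowScoreProfile,
    call_nols,
    candidate_scores,
    residue_profile,
)
from nolscan.sequence_io import SequenceRecord


def profile_from(scores, name="p"):
    return WindowScoreProfile(sequence_name=name, length=len(scores) + 12,
                              scores=tuple(scores))


def segments_from(scores, name="p"):
    return candidate_scores(profile_from(scores, name))


def brute_force_calls(segment_scores, threshold=0.8, seg_len=20):
    """Independent oracle: test every 20-mer, then union covered residues."""
    covered = set()
    for i, s in enumerate(segment_scores, start=1):
        if s >= threshold:
            covered.update(range(i, i + seg_len))
    intervals, run = [], None
    for pos in sorted(covered):
        if run and pos == run[1] + 1:
            run[1] = pos
        else:
            if run:
                intervals.append(tuple(run))
            run = [pos, pos]
    if run:
        intervals.append(tuple(run))
    return intervals


def test_all_ones_profile():
    segs = segments_from([1.0] * 20)  # L = 32
    assert len(segs.segment_scores) == 13
    assert all(s == pytest.approx(1.0) for s in segs.segment_scores)


def test_single_dropped_window_mean():
    segs = segments_from([1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1])
    assert segs.segment_scores[0] == pytest.approx(1.0)
    assert segs.segment_scores[1] == pytest.approx(7 / 8)


def test_short_profile_has_no_candidates():
    segs = segments_from([0.9] * 7)  # L = 19 < 20
    assert segs.segment_scores == ()


@given(st.lists(st.floats(0, 1), min_size=8, max_size=60))
def test_candidate_scores_equal_loop_oracle(scores):
    segs = segments_from(scores)
    for i, s in enumerate(segs.segment_scores):
        assert s == pytest.approx(float(np.mean(scores[i:i + 8])), abs=1e-12)


def test_single_positive_segment_gives_minimum_length_call():
    scores = [0.9] * 8 + [0.0] * 8  # only the first 8-window mean reaches 0.8
    intervals = call_nols(segments_from(scores))
    assert [(iv.start, iv.end) for iv in intervals] == [(1, 20)]
    assert len(intervals[0]) == 20


def test_full_merge_on_all_positive():
    scores = [1.0] * 20  # L = 32
    intervals = call_nols(segments_from(scores))
    assert [(iv.start, iv.end) for iv in intervals] == [(1, 32)]


def test_two_separated_runs():
    # positive segment starts {5..11, 40}; L must allow start 40
    seg = [0.0] * 47
    for i in list(range(5, 12)) + [40]:
        seg[i - 1] = 0.95
    segs = CandidateSegmentProfile("p", len(seg) + 19, tuple(seg))
    intervals = call_nols(segs)
    assert [(iv.start, iv.end) for iv in intervals] == [(5, 30), (40, 59)]


def test_called_intervals_carry_spanned_residues(trained_model):
    rec = SequenceRecord("p", "A" * 40)
    seg = tuple([0.9] * 2 + [0.0] * 19)
    intervals = call_nols(CandidateSegmentProfile("p", 40, seg), rec)
    assert intervals[0].sequence == rec.residues[0:21]


@given(st.lists(st.sampled_from([0.0, 0.5, 0.79, 0.8, 0.81, 0.95, 1.0]),
                min_size=1, max_size=288))
def test_call_nols_matches_brute_force_union(scores):
    """Lengths 13..300: calls equal the enumerate-then-union oracle."""
    segs = segments_from(scores)
    got = [(iv.start, iv.end) for iv in call_nols(segs)]
    assert got == brute_force_calls(segs.segment_scores)
    assert all(e - s + 1 >= 20 for s, e in got)
    # sorted and non-overlapping
    for (s1, e1), (s2, e2) in zip(got, got[1:]):
        assert e1 < s2


@given(st.lists(st.floats(0, 1), min_size=8, max_size=100))
def test_raising_threshold_never_extends_coverage(scores):
    segs = segments_from(scores)

    def covered(th):
        calls = call_nols(segs, params=Parameters(score_threshold=th))
        return sum(len(iv) for iv in calls)

    assert covered(0.9) <= covered(0.8) <= covered(0.5)


def test_residue_profile_padding_rule():
    segs = CandidateSegmentProfile("p", 21, (0.3, 0.7))
    prof = residue_profile(segs)
    assert prof == [0.3] + [0.7] * 20
    assert len(prof) == 21


def test_residue_profile_constant_and_undefined_cases():
    segs = CandidateSegmentProfile("p", 25, (0.4,) * 6)
    assert residue_profile(segs) == [0.4] * 25
    empty = CandidateSegmentProfile("p", 15, ())
    assert residue_profile(empty) == [0.0] * 15


@given(st.integers(min_value=20, max_value=120))
def test_residue_profile_length_equals_sequence_length(L):
    segs = CandidateSegmentProfile("p", L, tuple([0.5] * (L - 19)))
    assert len(residue_profile(segs)) == L
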