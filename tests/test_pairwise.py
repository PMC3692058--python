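import numpy as np
import pytest

from ribotherm import (
    classify_positions,
    cluster_onset,
    onset_temperature,
    render_comparison_text,
    specific_clusters,
)
from ribotherm.clustering import Cluster
from ribotherm.scan import SignificantPositions


def sig_from_sets(sets_by_temp: dict[int, set[int]], length: int, t1: int = 32,
                  t2: int = 39) -> SignificantPositions:
    temps = tuple(range(t1 + 1, t2 + 1))
    flags = np.zeros((len(temps), length), dtype=bool)
    diffs = np.zeros_like(flags, dtype=float)
    for r, t in enumerate(temps):
        for p in sets_by_temp.get(t, ()):
            flags[r, p - 1] = True
            diffs[r, p - 1] = 0.5
    return SignificantPositions(
        threshold_sd=3.0, temperatures=temps, flags=flags, diffs=diffs
    )


class TestClassifyPositions:
    def test_identical_inputs_all_shared(self):
        sig = sig_from_sets({39: {5, 6}, 35: {2}}, 10)
        cmp = classify_positions(sig, sig)
        assert cmp.shared_positions[39] == frozenset({5, 6})
        assert cmp.specific_positions_a[39] == frozenset()
        assert cmp.specific_positions_b[39] == frozenset()

    def test_partial_overlap(self):
        a = sig_from_sets({39: {5, 6}}, 10)
        b = sig_from_sets({39: {6, 7}}, 10)
        cmp = classify_positions(a, b)
        assert cmp.shared_positions[39] == frozenset({6})
        assert cmp.specific_positions_a[39] == frozenset({5})
        assert cmp.specific_positions_b[39] == frozenset({7})

    def test_empty_b_makes_all_specific(self):
        a = sig_from_sets({39: {1, 2, 3}}, 10)
        b = sig_from_sets({}, 10)
        cmp = classify_positions(a, b)
        assert cmp.specific_positions_a[39] == frozenset({1, 2, 3})
        assert cmp.shared_positions[39] == frozenset()

    def test_symmetry_under_swap(self):
        a = sig_from_sets({39: {1, 5}, 36: {2}}, 12)
        b = sig_from_sets({39: {5, 9}}, 12)
        ab, ba = classify_positions(a, b), classify_positions(b, a)
        for t in ab.temperatures:
            assert ab.shared_positions[t] == ba.shared_positions[t]
            assert ab.specific_positions_a[t] == ba.specific_positions_b[t]

    def test_shared_plus_specific_equals_significant(self):
        a = sig_from_sets({39: {1, 2, 5, 8}, 34: {3}}, 12)
        b = sig_from_sets({39: {2, 8, 11}}, 12)
        cmp = classify_positions(a, b)
        for t in cmp.temperatures:
            assert (
                len(cmp.shared_positions[t]) + len(cmp.specific_positions_a[t])
                == len(a.positions_at(t))
            )

    def test_mismatched_ranges_rejected(self):
        a = sig_from_sets({}, 10, t1=32, t2=39)
        b = sig_from_sets({}, 10, t1=30, t2=37)
        with pytest.raises(ValueError):
            classify_positions(a, b)


def span(start, end):
    return Cluster(start=start, end=end, members=tuple(range(start, end + 1)))


class TestSpecificClusters:
    def test_lone_cluster_is_specific(self):
        spec_a, spec_b = specific_clusters([span(100, 120)], [])
        assert [c.start for c in spec_a] == [100] and spec_b == []

    def test_single_position_overlap_disqualifies(self):
        spec_a, spec_b = specific_clusters([span(100, 120)], [span(120, 140)])
        assert spec_a == [] and spec_b == []

    def test_adjacent_disjoint_spans_both_specific(self):
        spec_a, spec_b = specific_clusters([span(100, 120)], [span(121, 140)])
        assert len(spec_a) == 1 and len(spec_b) == 1


class TestOnset:
    def test_onset_is_lowest_flagged_temperature(self):
        sig = sig_from_sets({36: {4}, 37: {4}, 38: {4}, 39: {4}}, 10)
        assert onset_temperature(sig, 4) == 36

    def test_never_significant_returns_none(self):
        sig = sig_from_sets({}, 10)
        assert onset_temperature(sig, 3) is None

    def test_top_only(self):
        sig = sig_from_sets({39: {7}}, 10)
        assert onset_temperature(sig, 7) == 39

    def test_cluster_onset_is_member_minimum(self):
        sig = sig_from_sets({35: {5}, 39: {5, 6, 7}}, 10)
        assert cluster_onset(sig, span(5, 7)) == 35

    def test_position_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            onset_temperature(sig_from_sets({}, 10), 11)


class TestRendering:
    def test_text_layout_contains_match_line_and_marks(self):
        a, b = "GGGAAACCCA", "GGGAAACCCU"
        cmp = classify_positions(
            sig_from_sets({39: {1, 2}}, 10), sig_from_sets({39: {2, 3}}, 10)
        )
        text = render_comparison_text(a, b, cmp, id_a="x", id_b="y")
        assert "|||||||||-" in text  # mismatch at the final position
        assert "o**" not in text.splitlines()[0]
        block39 = text.split("# elevated temperature 39 C")[1]
        lines = [l[2:] for l in block39.splitlines()]
        assert "o*........" in lines  # position 1 specific to A, 2 shared
        assert ".*o......." in lines  # position 3 specific to B
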