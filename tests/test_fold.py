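import random

import numpy as np
import pytest

from ribotherm import (
    FoldError,
    FoldOptions,
    RnaSequence,
    enumerate_structures,
    enumerated_pair_matrix,
    pairing_probabilities,
    reference_pair_matrix,
    vienna_pair_matrix,
)
from ribotherm.fold import pair_type


def seq(residues: str) -> RnaSequence:
    return RnaSequence(id="t", residues=residues)


class TestEnumeration:
    def test_unpairable_sequence_has_only_empty_structure(self):
        assert enumerate_structures(seq("AAAA")) == [frozenset()]

    def test_single_pair_hairpin(self):
        structures = enumerate_structures(seq("GAAAC"))
        assert sorted(structures, key=len) == [frozenset(), frozenset({(1, 5)})]

    def test_count_matches_independent_subset_enumeration(self):
        # independent oracle: filter all subsets of legal pairs for
        # disjointness and non-crossing
        import itertools

        s = seq("AGAAACUGC")
        pairs = [
            (i, j)
            for i in range(1, 10)
            for j in range(i + 4, 10)
            if pair_type(s.residues[i - 1], s.residues[j - 1])
        ]
        valid = 0
        for r in range(len(pairs) + 1):
            for combo in itertools.combinations(pairs, r):
                flat = [x for p in combo for x in p]
                if len(set(flat)) != len(flat):
                    continue
                if any(
                    a < c < b < d or c < a < d < b
                    for (a, b) in combo
                    for (c, d) in combo
                    if (a, b) < (c, d)
                ):
                    continue
                valid += 1
        assert len(enumerate_structures(s)) == valid

    def test_close_gu_rule_drops_isolated_gu_pairs(self):
        # only legal pair is G1-U5, which can never be stacked
        s = seq("GCCCU")
        assert len(enumerate_structures(s)) == 2
        assert enumerate_structures(s, FoldOptions(no_close_gu=True)) == [frozenset()]

    def test_length_cap(self):
        with pytest.raises(ValueError):
            enumerate_structures(seq("A" * 26))


class TestReferenceEngine:
    def test_matches_enumeration_on_random_sequences(self):
        rng = random.Random(11)
        for _ in range(10):
            n = rng.randint(5, 16)
            s = seq("".join(rng.choice("ACGU") for _ in range(n)))
            for opts in (FoldOptions(), FoldOptions(no_gu=True)):
                for t in (10, 37, 90):
                    engine = reference_pair_matrix(s, t, opts).P
                    oracle = enumerated_pair_matrix(s, t, opts).P
                    assert np.abs(engine - oracle).max() < 1e-9

    def test_unpairable_sequence_all_zero(self):
        p = pairing_probabilities(seq("AAAAAAAAAA"), 37)
        assert np.all(p == 0.0)

    def test_short_sequence_loop_constraint(self):
        assert np.all(reference_pair_matrix(seq("GAAC"), 37).P == 0.0)

    def test_no_gu_forbids_all_gu_pairs(self):
        s = seq("GUGUGUGUGU")
        assert np.all(pairing_probabilities(s, 37, FoldOptions(no_gu=True)) == 0.0)
        P = reference_pair_matrix(s, 37).P
        res = s.residues
        for i in range(len(s)):
            for j in range(len(s)):
                if P[i, j] > 0:
                    assert pair_type(res[i], res[j]) is not None
        Pn = reference_pair_matrix(s, 37, FoldOptions(no_gu=True)).P
        assert np.all(Pn == 0.0)

    def test_probabilities_within_unit_interval(self, hairpin_seq):
        for t in (0, 37, 99):
            p = pairing_probabilities(hairpin_seq, t)
            assert p.min() >= 0.0 and p.max() <= 1.0
            P = reference_pair_matrix(hairpin_seq, t).P
            assert np.allclose(P, P.T)
            assert P.sum(axis=1).max() <= 1.0 + 1e-9

    def test_heating_melts_weak_hairpin(self):
        s = seq("C" * 6 + "AAAAAAA" + "CCCC" + "UUUUUUU" + "C" * 6)
        cold = reference_pair_matrix(s, 10).P.sum()
        hot = reference_pair_matrix(s, 90).P.sum()
        assert hot < cold

    def test_temperature_continuity(self):
        s = seq("AAAAAAAACCCCUUUUUUUU")
        probs = [pairing_probabilities(s, t) for t in range(30, 46)]
        steps = [np.abs(b - a).max() for a, b in zip(probs, probs[1:])]
        assert max(steps) < 0.15  # smooth melting, no jumps

    def test_integer_temperature_required(self):
        with pytest.raises(TypeError):
            pairing_probabilities(seq("GGGAAAUCCC"), 37.5)


class TestBackends:
    def test_unknown_backend_rejected(self, hairpin_seq):
        with pytest.raises(FoldError):
            pairing_probabilities(hairpin_seq, 37, backend="nope")

    def test_injected_provider(self, hairpin_seq):
        p = pairing_probabilities(hairpin_seq, 37, backend="test-constant")
        assert np.all(p == 0.5)

    def test_vienna_adapter_hairpin(self, hairpin_seq):
        p = pairing_probabilities(hairpin_seq, 37, backend="vienna")
        assert p.shape == (len(hairpin_seq),)
        assert p.min() >= 0.0 and p.max() <= 1.0
        # the G-C stem must be strongly paired at 37 degC
        assert p[:4].min() > 0.5 and p[-4:].max() > 0.5

    def test_vienna_no_gu_removes_gu_only_pairing(self):
        s = seq("GGGGGAAAAUUUUU")
        default = pairing_probabilities(s, 37, backend="vienna")
        no_gu = pairing_probabilities(s, 37, FoldOptions(no_gu=True), backend="vienna")
        P = vienna_pair_matrix(s, 37, FoldOptions(no_gu=True)).P
        res = s.residues
        for i in range(len(s)):
            for j in range(len(s)):
                if P[i, j] > 1e-12:
                    assert pair_type(res[i], res[j]) != "GU"
        assert default.shape == no_gu.shape
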