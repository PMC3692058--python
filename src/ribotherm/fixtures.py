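"""Deterministic synthetic sequences with designed thermal behaviour.

These generators emulate, at desk scale, the situations the pipeline is
built for, under the reference engine's energy model:

* ``stable-hairpin`` — a G-C stem that stays paired across the default
  32-39 degC window (paired probability > 0.9 at both ends).
* ``melting-hairpin`` — a 10-bp A-U stem whose pairing probability falls
  steeply inside the window, so its positions exceed the 3-SD threshold
  of the combined difference data set.
* ``pair-with-specific-cluster`` — two sequences separated by one
  substitution in the middle of one of two A-U stems. The intact stem
  yields a shared cluster; the broken stem yields a cluster specific to
  the first sequence. A third, neutral variant (substitution in an inert
  spacer) leaves both clusters shared.

The A-U stem arms are fixed patterned 10-mers chosen so that, under the
minimum stacking run needed for stability, neither arm can form a
competing helix with the other hairpin's arms (worst cross-register
stacked run of 4, free energy > +2.5 kcal/mol at 32 degC). Spacers are C
(pairs only with G, which the melting elements avoid); the stable stem is
G/C only. The seed varies inert spacer lengths, never the designed
elements.
"""

from __future__ import annotations

import numpy as np

from .sequences import RnaSequence

_COMP_AU = {"A": "U", "U": "A"}

# Patterned A/U stem arms (5'->3'), cross-talk checked at design time.
ARM_X = "AUUUUAAUAA"
ARM_Y = "AAAUUAUAUU"
LOOP = "CCCC"
STABLE_STEM = "G" * 8 + LOOP + "C" * 8

FIXTURE_KINDS = ("stable-hairpin", "melting-hairpin", "pair-with-specific-cluster")


def _rc_au(arm: str) -> str:
    return "".join(_COMP_AU[c] for c in reversed(arm))


def _hairpin(arm: str) -> str:
    return arm + LOOP + _rc_au(arm)


def _spacers(rng: np.random.Generator, k: int, base: str = "C") -> list[str]:
    return [base * int(rng.integers(8, 15)) for _ in range(k)]


def make_fixture(kind: str, seed: int = 0):
    """Build the named fixture; returns one or three RnaSequence objects.

    ``pair-with-specific-cluster`` returns (seq_a, seq_b, seq_neutral):
    seq_b breaks the first A-U stem mid-arm (A -> C), seq_neutral carries
    a C -> G substitution in an inert spacer.
    """
    rng = np.random.default_rng(seed)
    if kind == "stable-hairpin":
        # A spacers are inert here: the sequence contains no U.
        s1, s2 = ("A" * int(rng.integers(8, 15)) for _ in range(2))
        residues = s1 + "G" * 8 + "AAAA" + "C" * 8 + s2
        return RnaSequence(id=f"stable_hairpin_{seed}", residues=residues)
    if kind == "melting-hairpin":
        s1, s2, s3 = _spacers(rng, 3)
        residues = s1 + _hairpin(ARM_X) + s2 + STABLE_STEM + s3
        return RnaSequence(id=f"melting_hairpin_{seed}", residues=residues)
    if kind == "pair-with-specific-cluster":
        s1, s2, s3, s4 = _spacers(rng, 4)
        parts = [s1, _hairpin(ARM_X), s2, _hairpin(ARM_Y), s3, STABLE_STEM, s4]
        residues = "".join(parts)
        # middle of the first stem's 5' arm (position 6 of ARM_X)
        break_pos = len(s1) + 6
        broken = residues[: break_pos - 1] + "C" + residues[break_pos:]
        neutral_pos = len(residues) - len(s4) + 3  # inside the last spacer
        neutral = residues[: neutral_pos - 1] + "G" + residues[neutral_pos:]
        return (
            RnaSequence(id=f"pair_a_{seed}", residues=residues),
            RnaSequence(id=f"pair_b_{seed}", residues=broken),
            RnaSequence(id=f"pair_neutral_{seed}", residues=neutral),
        )
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def stem_positions(seq: RnaSequence, kind: str) -> list[int]:
    """1-based positions of the designed stem(s) for assertion in tests."""
    res = seq.residues
    if kind == "stable-hairpin":
        start = res.index("G" * 8) + 1
        return list(range(start, start + 8)) + list(
            range(start + 12, start + 20)
        )
    if kind in ("melting-hairpin", "pair-with-specific-cluster"):
        start = res.index(ARM_X) + 1
        return list(range(start, start + 24))
    raise ValueError(kind)


def random_sequence(length: int, seed: int = 0, id: str = "random") -> RnaSequence:
    """Uniform random RNA sequence (for scale/size checks)."""
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list("ACGU"), size=length))
    return RnaSequence(id=f"{id}_{length}", residues=residues)
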