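"""In-silico mutant generation for the specificity analysis.

Given that N substitutions separate sequence A from sequence B, a data
set of derivatives of A is generated, each carrying exactly N
substitutions. Two regimes:

* coding (default): synonymous single-base codon changes only, so every
  mutant translates to the parent protein (standard genetic code,
  frame 1 from position 1);
* non-coding: substitutions at random positions whose (from -> to) types
  are drawn from the substitution spectrum observed between A and B.

Sampling is seeded and fully deterministic; independent mutants are drawn
with replacement, so duplicate mutants are permitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .sequences import RnaSequence, SubstitutionSpectrum

DEFAULT_N_MUTANTS = 100
_BASES = "ACGU"


class MutagenError(ValueError):
    """Raised when the requested mutant set cannot be generated."""


@dataclass(frozen=True)
class MutantSet:
    parent_id: str
    n_substitutions: int
    regime: str  # "coding" | "noncoding"
    sequences: tuple[RnaSequence, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.sequences)


def translate(residues: str) -> str:
    """Standard-code frame-1 translation (stop codons rendered as '*')."""
    return str(Seq(residues).translate())


def _synonymous_options(residues: str) -> dict[int, list[str]]:
    """Per 1-based position: replacement bases that keep the protein.

    Only single-base changes within one codon are considered; each option
    is synonymous on its own against the current codon.
    """
    options: dict[int, list[str]] = {}
    for c0 in range(0, len(residues), 3):
        codon = residues[c0 : c0 + 3]
        aa = translate(codon)
        for off in range(3):
            subs = []
            for b in _BASES:
                if b == codon[off]:
                    continue
                alt = codon[:off] + b + codon[off + 1 :]
                if translate(alt) == aa:
                    subs.append(b)
            if subs:
                options[c0 + off + 1] = subs
    return options


def synonymous_mutants(
    parent: RnaSequence,
    n_subs: int,
    n_mutants: int = DEFAULT_N_MUTANTS,
    seed: int = 0,
) -> MutantSet:
    """Mutants carrying exactly ``n_subs`` synonymous substitutions each.

    Substitutions are sampled sequentially; after each accepted change the
    synonymous options are re-evaluated against the mutated sequence, so
    two hits within one codon can never combine into a missense change.
    Positions are hit at most once per mutant, keeping the Hamming
    distance to the parent exactly ``n_subs``.
    """
    if len(parent) % 3 != 0:
        raise MutagenError(
            f"coding sequence length {len(parent)} is not divisible by 3"
        )
    if n_subs < 1:
        raise MutagenError("need at least one substitution to test")
    if len(_synonymous_options(parent.residues)) < n_subs:
        raise MutagenError(
            f"parent admits fewer than {n_subs} synonymous substitution sites"
        )
    rng = np.random.default_rng(seed)
    protein = translate(parent.residues)
    parent_options = _synonymous_options(parent.residues)
    mutants = []
    for m in range(n_mutants):
        residues = list(parent.residues)
        used: set[int] = set()
        options = dict(parent_options)
        for _ in range(n_subs):
            candidates = sorted(p for p in options if p not in used)
            if not candidates:
                raise MutagenError(
                    "ran out of synonymous sites while building a mutant"
                )
            p = candidates[rng.integers(len(candidates))]
            subs = options[p]
            residues[p - 1] = subs[rng.integers(len(subs))]
            used.add(p)
            # refresh options for the mutated codon only
            c0 = (p - 1) // 3 * 3
            codon = "".join(residues[c0 : c0 + 3])
            fresh = _synonymous_options(codon)
            for off in range(3):
                q = c0 + off + 1
                if off + 1 in fresh:
                    options[q] = fresh[off + 1]
                else:
                    options.pop(q, None)
        seq = "".join(residues)
        assert translate(seq) == protein
        mutants.append(
            RnaSequence(id=f"{parent.id or 'parent'}_syn{m + 1}", residues=seq,
                        is_coding=True)
        )
    return MutantSet(
        parent_id=parent.id,
        n_substitutions=n_subs,
        regime="coding",
        sequences=tuple(mutants),
        seed=seed,
    )


def spectrum_mutants(
    parent: RnaSequence,
    spectrum: SubstitutionSpectrum,
    n_mutants: int = DEFAULT_N_MUTANTS,
    seed: int = 0,
    max_retries: int = 1000,
) -> MutantSet:
    """Mutants mimicking the observed substitution-type frequencies.

    Each mutant receives exactly ``spectrum.count`` substitutions at
    distinct positions. For every substitution a (from -> to) type is
    drawn from the spectrum; a position with the matching current base is
    then chosen uniformly. Types with no eligible position left are
    redrawn (bounded rejection sampling).
    """
    if spectrum.count < 1:
        raise MutagenError("spectrum is empty; the sequences are identical")
    types = sorted(spectrum.type_frequencies)
    probs = np.array([spectrum.type_frequencies[t] for t in types])
    rng = np.random.default_rng(seed)
    mutants = []
    for m in range(n_mutants):
        residues = list(parent.residues)
        used: set[int] = set()
        for _ in range(spectrum.count):
            for _attempt in range(max_retries):
                ti = rng.choice(len(types), p=probs)
                frm, to = types[ti]
                eligible = [
                    i
                    for i, b in enumerate(residues)
                    if b == frm and (i + 1) not in used
                ]
                if eligible:
                    break
            else:
                raise MutagenError(
                    f"no position available for any drawn substitution type "
                    f"after {max_retries} retries"
                )
            i = eligible[rng.integers(len(eligible))]
            residues[i] = to
            used.add(i + 1)
        mutants.append(
            RnaSequence(
                id=f"{parent.id or 'parent'}_mut{m + 1}",
                residues="".join(residues),
                is_coding=parent.is_coding,
            )
        )
    return MutantSet(
        parent_id=parent.id,
        n_substitutions=spectrum.count,
        regime="noncoding",
        sequences=tuple(mutants),
        seed=seed,
    )
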