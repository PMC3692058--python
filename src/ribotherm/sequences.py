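"""Sequence input, validation and substitution bookkeeping.

Sequences are plain RNA strings over {A, C, G, U}. DNA input is accepted
and every T is converted to U; mixed case and surrounding whitespace are
tolerated. Degenerate IUPAC codes are rejected. All reported coordinates
throughout the package are 1-based and inclusive.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MAX_LENGTH = 9999
MIN_TEMPERATURE = 0
MAX_TEMPERATURE = 99
MAX_SPAN = 20  # maximal t2 - t1 + 1

_ALPHABET = frozenset("ACGU")


class SequenceError(ValueError):
    """Raised for malformed or out-of-limit sequence input."""


class TemperatureRangeError(ValueError):
    """Raised for an invalid temperature range."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence.

    Parameters
    ----------
    id
        FASTA header (may be empty for headerless input).
    residues
        Uppercase RNA string over {A, C, G, U}.
    is_coding
        Whether the sequence is treated as protein coding (frame 1).
        Controls the mutagenesis regime downstream.
    """

    id: str
    residues: str
    is_coding: bool = True

    def __post_init__(self) -> None:
        if not 1 <= len(self.residues) <= MAX_LENGTH:
            raise SequenceError(
                f"sequence length {len(self.residues)} outside 1..{MAX_LENGTH}"
            )
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise SequenceError(
                f"illegal character(s) {sorted(bad)}; allowed: A, C, G, U, T"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TemperatureRange:
    """Integer temperature window [t1, t2] in degrees Celsius."""

    t1: int
    t2: int

    @property
    def temperatures(self) -> list[int]:
        return list(range(self.t1, self.t2 + 1))

    @property
    def span(self) -> int:
        return self.t2 - self.t1 + 1


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Number and type frequencies of substitutions between two sequences.

    ``type_frequencies`` maps ordered (from_base, to_base) pairs to their
    relative frequency among the mismatch positions; it is empty when the
    sequences are identical.
    """

    count: int
    type_frequencies: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: tuple[int, ...] = ()  # 1-based mismatch positions


def _normalize(raw: str) -> str:
    return raw.strip().upper().replace("T", "U")


def read_sequence(fasta_text: str, is_coding: bool = True) -> RnaSequence:
    """Parse one sequence from FASTA text or a bare sequence string.

    T is replaced by U and case is folded to uppercase. Exactly one record
    is allowed; headerless input gets an empty id.
    """
    text = fasta_text.strip()
    if not text:
        raise SequenceError("empty input")
    if text.startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if len(records) != 1:
            raise SequenceError(f"expected exactly one FASTA record, got {len(records)}")
        header = records[0].description
        residues = _normalize(str(records[0].seq))
    else:
        header = ""
        residues = _normalize("".join(text.split()))
    return RnaSequence(id=header, residues=residues, is_coding=is_coding)


def read_fasta_file(path, is_coding: bool = True) -> RnaSequence:
    """Read a single-record FASTA file."""
    with open(path) as fh:
        return read_sequence(fh.read(), is_coding=is_coding)


def write_fasta(records: list[RnaSequence], path) -> None:
    """Write sequences as multi-record FASTA (used for mutant export)."""
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id or f"seq{i + 1}", description="")
        for i, r in enumerate(records)
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def validate_pair(a: RnaSequence, b: RnaSequence) -> None:
    """Require the two sequences to have equal length."""
    if len(a) != len(b):
        raise SequenceError(
            f"sequences must have equal length ({len(a)} != {len(b)})"
        )


def validate_range(r: TemperatureRange) -> None:
    """Enforce the temperature-window limits.

    Bounds are 0..99 deg C, t1 < t2, and the window width t2 - t1 + 1 may be
    at most 20 (so 30-49 is accepted and 30-50 is not).
    """
    if not (MIN_TEMPERATURE <= r.t1 <= MAX_TEMPERATURE):
        raise TemperatureRangeError(f"t1={r.t1} outside {MIN_TEMPERATURE}..{MAX_TEMPERATURE}")
    if not (MIN_TEMPERATURE <= r.t2 <= MAX_TEMPERATURE):
        raise TemperatureRangeError(f"t2={r.t2} outside {MIN_TEMPERATURE}..{MAX_TEMPERATURE}")
    if r.t1 >= r.t2:
        raise TemperatureRangeError(f"t1={r.t1} must be below t2={r.t2}")
    if r.span > MAX_SPAN:
        raise TemperatureRangeError(
            f"temperature span t2-t1+1={r.span} exceeds the maximum of {MAX_SPAN}"
        )


def substitution_spectrum(a: RnaSequence, b: RnaSequence) -> SubstitutionSpectrum:
    """Count mismatches between two equal-length sequences.

    Returns the Hamming distance and the relative frequency of each ordered
    substitution type a_i -> b_i over the mismatch positions.
    """
    validate_pair(a, b)
    counts: Counter[tuple[str, str]] = Counter()
    positions: list[int] = []
    for i, (x, y) in enumerate(zip(a.residues, b.residues), start=1):
        if x != y:
            counts[(x, y)] += 1
            positions.append(i)
    n = sum(counts.values())
    freqs = {k: v / n for k, v in counts.items()} if n else {}
    return SubstitutionSpectrum(count=n, type_frequencies=freqs, positions=tuple(positions))
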