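"""Equilibrium base-pairing probabilities at a given temperature.

Two interchangeable providers compute, for every nucleotide i, the
probability p(i) that it is paired with any partner in the Boltzmann
ensemble of secondary structures:

* ``"vienna"`` — adapter around the ViennaRNA partition function (RNAfold's
  machinery), honouring the G-U options via ``noGU``/``noGUclosure``.
* ``"reference"`` — a built-in engine over a deliberately simple
  nucleation-and-zipping energy model: one enthalpy/entropy constant per
  pair type (G-C stronger than A-U stronger than G-U) plus a single
  temperature-dependent stacking weight for adjacent pairs. It is exactly
  checkable against exhaustive structure enumeration, which ViennaRNA's
  full nearest-neighbour model is not; it does not reproduce ViennaRNA
  numerics and is not meant to.

Any callable with the provider signature can be registered, which is how
tests inject fully deterministic synthetic profiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from . import _kernels
from .sequences import RnaSequence

GAS_CONSTANT = 0.0019872  # kcal / (mol K)
CELSIUS_OFFSET = 273.15
MIN_LOOP = 3  # minimum number of unpaired bases in a hairpin loop
MAX_ENUMERATION_LENGTH = 25

#: Toy per-pair enthalpies/entropies (kcal/mol and kcal/mol/K). A-U and G-U
#: pairs carry a nucleation penalty and are only viable inside stacked
#: helices; the stack term carries the bulk of the temperature dependence,
#: so helix melting is cooperative and a single substitution can melt a
#: marginal stem. Constants are chosen so a ~10-bp A-U stem melts within
#: the default 32-39 degC window while G-C stems stay formed.
PAIR_DH = {"GC": -3.0, "AU": 5.2, "GU": 6.5}
PAIR_DS = {"GC": -0.008, "AU": 0.0, "GU": 0.0}
STACK_DH = -19.56
STACK_DS = -0.0444

_PAIR_TYPE = {
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("A", "U"): "AU", ("U", "A"): "AU",
    ("G", "U"): "GU", ("U", "G"): "GU",
}


class FoldError(RuntimeError):
    """Raised when a folding backend fails."""


@dataclass(frozen=True)
class FoldOptions:
    """G-U wobble-pair handling.

    no_gu forbids G-U pairs entirely; no_close_gu forbids them at helix
    ends (a G-U pair must be stacked on an adjacent pair).
    """

    no_gu: bool = False
    no_close_gu: bool = False


@dataclass(frozen=True)
class PairMatrix:
    """Symmetric matrix of equilibrium pair probabilities P(i, j)."""

    n: int
    P: np.ndarray  # (n, n), 0-indexed

    def paired_vector(self) -> np.ndarray:
        """p(i) = sum_j P(i, j), clipped into [0, 1]."""
        return np.clip(self.P.sum(axis=1), 0.0, 1.0)


def pair_type(x: str, y: str) -> str | None:
    return _PAIR_TYPE.get((x, y))


def pair_weight(ptype: str, kelvin: float) -> float:
    dg = PAIR_DH[ptype] - kelvin * PAIR_DS[ptype]
    return math.exp(-dg / (GAS_CONSTANT * kelvin))


def stack_weight(kelvin: float) -> float:
    dg = STACK_DH - kelvin * STACK_DS
    return math.exp(-dg / (GAS_CONSTANT * kelvin))


def _weight_matrices(seq: str, kelvin: float, opts: FoldOptions):
    """(n+2, n+2) 1-based pair-weight matrix and strict-GU flag matrix."""
    n = len(seq)
    q = np.zeros((n + 2, n + 2))
    gu_strict = np.zeros((n + 2, n + 2), dtype=np.bool_)
    weights = {t: pair_weight(t, kelvin) for t in PAIR_DH}
    for i in range(1, n + 1):
        for j in range(i + MIN_LOOP + 1, n + 1):
            t = pair_type(seq[i - 1], seq[j - 1])
            if t is None or (t == "GU" and opts.no_gu):
                continue
            q[i, j] = weights[t]
            if t == "GU" and opts.no_close_gu:
                gu_strict[i, j] = True
    return q, gu_strict


def reference_pair_matrix(
    seq: RnaSequence, temperature_celsius: int, opts: FoldOptions = FoldOptions()
) -> PairMatrix:
    """Pair-probability matrix from the built-in inside-outside recursions.

    With ``no_close_gu`` the recursion admits a G-U pair only when stacked
    on its *inner* neighbour; the enumeration oracle implements the full
    helix-end rule (inner or outer neighbour). The approximation is
    confined to this engine and documented.
    """
    n = len(seq)
    if n < MIN_LOOP + 2:
        return PairMatrix(n=n, P=np.zeros((n, n)))
    kelvin = temperature_celsius + CELSIUS_OFFSET
    q, gu_strict = _weight_matrices(seq.residues, kelvin, opts)
    sigma = stack_weight(kelvin)

    logq = np.where(q > 0.0, np.log(np.maximum(q, 1e-300)), _kernels.NEG_INF)
    wmax = _kernels.max_weight_log(logq, math.log(sigma))
    slog = max(0.0, wmax / n)

    Z = Zb = None
    for _ in range(40):
        s = math.exp(slog)
        Z, Zb = _kernels.inside(q, gu_strict, sigma, s)
        if not (np.isfinite(Z).all() and np.isfinite(Zb).all()):
            slog += 720.0 / n
        elif Z[1, n] == 0.0:
            slog -= 360.0 / n
        else:
            break
    else:
        raise FoldError("partition function scaling failed to converge")
    bZ, bB = _kernels.outside(q, gu_strict, sigma, s, Z, Zb)
    if not (np.isfinite(bZ).all() and np.isfinite(bB).all()):
        raise FoldError("outside recursion overflowed; sequence too heterogeneous")
    P = (bB[1 : n + 1, 1 : n + 1] * Zb[1 : n + 1, 1 : n + 1]) / Z[1, n]
    P = np.clip(P, 0.0, 1.0)
    P = P + P.T
    return PairMatrix(n=n, P=P)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (small sequences only)
# ---------------------------------------------------------------------------

def _legal_pairs(seq: str, opts: FoldOptions) -> list[tuple[int, int]]:
    n = len(seq)
    out = []
    for i, j in itertools.combinations(range(1, n + 1), 2):
        if j - i <= MIN_LOOP:
            continue
        t = pair_type(seq[i - 1], seq[j - 1])
        if t is None or (t == "GU" and opts.no_gu):
            continue
        out.append((i, j))
    return out


def enumerate_structures(
    seq: RnaSequence, opts: FoldOptions = FoldOptions()
) -> list[frozenset[tuple[int, int]]]:
    """Every pseudoknot-free set of non-crossing legal pairs (loop >= 3).

    Includes the empty structure. Under ``no_close_gu``, structures with a
    G-U pair lacking an adjacent stacked neighbour (inner or outer) are
    removed. Intended as a test oracle; limited to short sequences.
    """
    n = len(seq)
    if n > MAX_ENUMERATION_LENGTH:
        raise ValueError(f"sequence of length {n} too long to enumerate")
    pairs = _legal_pairs(seq.residues, opts)
    pairset = set(pairs)

    def recurse(i: int, j: int) -> list[frozenset]:
        if j - i < MIN_LOOP + 1:
            return [frozenset()]
        structures = list(recurse(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (i, k) in pairset:
                for left in recurse(i + 1, k - 1):
                    for right in recurse(k + 1, j):
                        structures.append(frozenset({(i, k)}) | left | right)
        return structures

    structures = recurse(1, n)
    if opts.no_close_gu:
        seqs = seq.residues

        def ok(struct: frozenset) -> bool:
            for (i, j) in struct:
                if pair_type(seqs[i - 1], seqs[j - 1]) == "GU":
                    if (i + 1, j - 1) not in struct and (i - 1, j + 1) not in struct:
                        return False
            return True

        structures = [s for s in structures if ok(s)]
    return structures


def structure_weight(seq: str, structure: Iterable[tuple[int, int]], kelvin: float) -> float:
    """Boltzmann weight: product of pair weights and per-stack weights."""
    struct = set(structure)
    w = 1.0
    sigma = stack_weight(kelvin)
    for (i, j) in struct:
        w *= pair_weight(pair_type(seq[i - 1], seq[j - 1]), kelvin)
        if (i + 1, j - 1) in struct:
            w *= sigma
    return w


def enumerated_pair_matrix(
    seq: RnaSequence, temperature_celsius: int, opts: FoldOptions = FoldOptions()
) -> PairMatrix:
    """Boltzmann-averaged pair frequencies over the enumerated ensemble."""
    n = len(seq)
    kelvin = temperature_celsius + CELSIUS_OFFSET
    P = np.zeros((n, n))
    total = 0.0
    for struct in enumerate_structures(seq, opts):
        w = structure_weight(seq.residues, struct, kelvin)
        total += w
        for (i, j) in struct:
            P[i - 1, j - 1] += w
    P /= total
    return PairMatrix(n=n, P=P + P.T)


# ---------------------------------------------------------------------------
# ViennaRNA adapter
# ---------------------------------------------------------------------------

def vienna_version() -> str | None:
    try:
        import RNA
    except ImportError:
        return None
    return getattr(RNA, "__version__", "unknown")


def vienna_pair_matrix(
    seq: RnaSequence, temperature_celsius: int, opts: FoldOptions = FoldOptions()
) -> PairMatrix:
    """Equilibrium pair probabilities from the ViennaRNA partition function."""
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - bindings present in CI image
        raise FoldError(
            "ViennaRNA python bindings not available; use backend='reference'"
        ) from exc
    md = RNA.md()
    md.temperature = float(temperature_celsius)
    md.noGU = 1 if opts.no_gu else 0
    md.noGUclosure = 1 if opts.no_close_gu else 0
    fc = RNA.fold_compound(seq.residues, md)
    fc.pf()
    bpp = np.asarray(fc.bpp())  # (n+1, n+1), upper triangle, 1-based
    n = len(seq)
    P = np.zeros((n, n))
    upper = bpp[1:, 1:]
    P = np.triu(upper, k=1)
    return PairMatrix(n=n, P=P + P.T)


# ---------------------------------------------------------------------------
# Provider registry
# ---------------------------------------------------------------------------

Provider = Callable[[RnaSequence, int, FoldOptions], np.ndarray]

_PROVIDERS: dict[str, Provider] = {}


def register_provider(name: str, provider: Provider) -> None:
    """Register a pairing-probability provider under ``name``.

    A provider maps (sequence, temperature_celsius, options) to the length-n
    vector p(i) of paired-state probabilities.
    """
    _PROVIDERS[name] = provider


def available_backends() -> list[str]:
    return sorted(_PROVIDERS)


register_provider(
    "reference",
    lambda seq, t, opts: reference_pair_matrix(seq, t, opts).paired_vector(),
)
register_provider(
    "vienna",
    lambda seq, t, opts: vienna_pair_matrix(seq, t, opts).paired_vector(),
)


def pairing_probabilities(
    seq: RnaSequence,
    temperature_celsius: int,
    opts: FoldOptions = FoldOptions(),
    backend: str = "reference",
) -> np.ndarray:
    """Per-nucleotide paired-state probabilities p(i) at one temperature."""
    if not isinstance(temperature_celsius, (int, np.integer)):
        raise TypeError("temperature must be an integer degree Celsius")
    if backend not in _PROVIDERS:
        raise FoldError(f"unknown backend {backend!r}; available: {available_backends()}")
    p = np.asarray(_PROVIDERS[backend](seq, int(temperature_celsius), opts), dtype=float)
    if p.shape != (len(seq),):
        raise FoldError(f"backend {backend!r} returned shape {p.shape}, expected ({len(seq)},)")
    return p
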