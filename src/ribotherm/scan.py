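"""Temperature scan, combined difference data set, and outlier calling.

For a window [t1, t2] the scan computes one paired-state probability
vector per integer temperature. Differences d(t, i) = p_t(i) - p_t1(i)
for every elevated temperature t in (t1, t2] are pooled into one combined
data set of (t2 - t1) * L values; a position is called significant at
temperature t when |d(t, i) - mean| > k * SD of that combined set
(k = 3 by default). The SD is the population SD of the combined vector —
the data set is the complete population of computed differences — so
results are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fold import FoldOptions, pairing_probabilities
from .sequences import RnaSequence, TemperatureRange, validate_range

DEFAULT_THRESHOLD_SD = 3.0


@dataclass(frozen=True)
class PairingProfile:
    """Matrix of p_t(i): one row per integer temperature in [t1, t2]."""

    temperatures: tuple[int, ...]
    matrix: np.ndarray  # (n_temps, L)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class DiffDataset:
    """Probability differences against the base temperature.

    ``diffs`` has one row per elevated temperature t1+1 .. t2 and holds
    d(t, i) = p_t(i) - p_t1(i); ``combined`` is the flattened pool of all
    (t2 - t1) * L values with its mean and population SD.
    """

    temperatures: tuple[int, ...]  # elevated temperatures only
    base_temperature: int
    diffs: np.ndarray  # (n_temps - 1, L)
    combined: np.ndarray = field(repr=False)
    mean: float = 0.0
    sd: float = 0.0


@dataclass(frozen=True)
class SignificantPositions:
    """Boolean significance flags per (elevated temperature, position)."""

    threshold_sd: float
    temperatures: tuple[int, ...]  # elevated temperatures
    flags: np.ndarray  # (n_temps - 1, L) boolean
    diffs: np.ndarray = field(repr=False)  # same shape, the underlying d(t, i)

    @property
    def per_temperature(self) -> dict[int, frozenset[int]]:
        """1-based significant positions for each elevated temperature."""
        return {
            t: frozenset((np.flatnonzero(self.flags[r]) + 1).tolist())
            for r, t in enumerate(self.temperatures)
        }

    def positions_at(self, t: int) -> frozenset[int]:
        r = self.temperatures.index(t)
        return frozenset((np.flatnonzero(self.flags[r]) + 1).tolist())

    @property
    def top_temperature(self) -> int:
        return self.temperatures[-1]

    @property
    def increase_set(self) -> frozenset[int]:
        """Positions significant at the top difference with d > 0."""
        row = self.flags[-1] & (self.diffs[-1] > 0)
        return frozenset((np.flatnonzero(row) + 1).tolist())

    @property
    def decrease_set(self) -> frozenset[int]:
        """Positions significant at the top difference with d < 0."""
        row = self.flags[-1] & (self.diffs[-1] < 0)
        return frozenset((np.flatnonzero(row) + 1).tolist())


def scan(
    seq: RnaSequence,
    trange: TemperatureRange,
    opts: FoldOptions = FoldOptions(),
    backend: str = "reference",
) -> PairingProfile:
    """Paired-state probabilities at every integer temperature in the window."""
    validate_range(trange)
    rows = []
    for t in trange.temperatures:
        try:
            rows.append(pairing_probabilities(seq, t, opts, backend=backend))
        except Exception as exc:
            raise RuntimeError(
                f"backend {backend!r} failed at {t} degC for sequence {seq.id!r}"
            ) from exc
    return PairingProfile(
        temperatures=tuple(trange.temperatures), matrix=np.vstack(rows)
    )


def diff_dataset(profile: PairingProfile) -> DiffDataset:
    """Pool the probability differences of all elevated temperatures.

    The base-vs-base zero row is not part of the data set: for L = 1000 and
    a 32-39 degC window the combined vector holds exactly 7 * 1000 values.
    """
    if profile.matrix.shape[0] < 2:
        raise ValueError("need at least two temperatures to form differences")
    diffs = profile.matrix[1:] - profile.matrix[0]
    combined = diffs.ravel()
    return DiffDataset(
        temperatures=tuple(profile.temperatures[1:]),
        base_temperature=profile.temperatures[0],
        diffs=diffs,
        combined=combined,
        mean=float(combined.mean()),
        sd=float(combined.std()),  # population SD
    )


def significant_positions(
    ds: DiffDataset, threshold_sd: float = DEFAULT_THRESHOLD_SD
) -> SignificantPositions:
    """Flag cells more than ``threshold_sd`` SDs away from the pooled mean.

    A temperature-insensitive input (SD = 0) yields no significant
    positions rather than flagging everything.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if ds.sd == 0.0:
        flags = np.zeros_like(ds.diffs, dtype=bool)
    else:
        flags = np.abs(ds.diffs - ds.mean) > threshold_sd * ds.sd
    return SignificantPositions(
        threshold_sd=threshold_sd,
        temperatures=ds.temperatures,
        flags=flags,
        diffs=ds.diffs,
    )
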