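"""DBSCAN clustering of significant positions along the sequence axis.

Positions live on the 1-D integer line with distance |a - b|. A core
point has at least ``min_pts`` positions (itself included) within
``eps``; clusters are the maximal density-connected sets and everything
else is noise. Defaults eps = 11, min_pts = 5. Input positions are sorted
ascending before clustering, which pins DBSCAN's only order dependence
(border-point ties) to a deterministic left-to-right assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

DEFAULT_EPS = 11
DEFAULT_MIN_PTS = 5


@dataclass(frozen=True)
class DbscanParams:
    eps: int = DEFAULT_EPS
    min_pts: int = DEFAULT_MIN_PTS

    def __post_init__(self) -> None:
        if self.eps < 1 or self.min_pts < 1:
            raise ValueError("eps and min_pts must be >= 1")


@dataclass(frozen=True)
class Cluster:
    """A cluster of significant positions: inclusive 1-based span.

    density = number of member positions / span length.
    """

    start: int
    end: int
    members: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def density(self) -> float:
        return len(self.members) / self.length

    def overlaps(self, other: "Cluster") -> bool:
        """Span intersection by at least one position."""
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class ClusterSummary:
    n_clusters: int
    avg_density: float | None
    avg_length: float | None


def dbscan_1d(positions, params: DbscanParams = DbscanParams()) -> list[Cluster]:
    """Standard DBSCAN on 1-D integer positions; clusters sorted by start."""
    pos = np.asarray(sorted(set(int(p) for p in positions)), dtype=float)
    if pos.size == 0:
        return []
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(
        pos.reshape(-1, 1)
    )
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        members = tuple(int(p) for p in pos[labels == lab])
        clusters.append(Cluster(start=members[0], end=members[-1], members=members))
    return sorted(clusters, key=lambda c: c.start)


def cluster_summary(clusters: list[Cluster]) -> ClusterSummary:
    """Unweighted means of density and length over the clusters."""
    if not clusters:
        return ClusterSummary(n_clusters=0, avg_density=None, avg_length=None)
    return ClusterSummary(
        n_clusters=len(clusters),
        avg_density=float(np.mean([c.density for c in clusters])),
        avg_length=float(np.mean([c.length for c in clusters])),
    )


def density_profile(positions, seq_length: int, eps: int = DEFAULT_EPS) -> np.ndarray:
    """Sliding-window density of significant positions, in percent.

    A window of size 2*eps + 1 moves in steps of one position; entry s
    (0-indexed window start s+1) is the percentage of window positions
    that are significant. A sequence shorter than the window falls back to
    a single full-sequence window.
    """
    window = 2 * eps + 1
    mask = np.zeros(seq_length)
    for p in positions:
        mask[p - 1] = 1.0
    if seq_length < window:
        return np.array([100.0 * mask.mean()])
    kernel = np.ones(window)
    counts = np.convolve(mask, kernel, mode="valid")
    return 100.0 * counts / window
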