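"""Exact binomial specificity tests for sequence-specific clusters.

For a sequence-specific cluster, k of the n in-silico mutants have at
least one cluster whose span overlaps the target span by >= 1 position.

* disappear (cluster in the first sequence, absent in the second): the
  composite null is that the cluster's persistence probability is below
  95%; the exact test is evaluated at the boundary p0 = 0.95 with the
  upper tail P(X >= k). A small p-value means the cluster is unlikely to
  disappear under random mutation sets.
* appear (cluster in the second sequence, absent in the first): the null
  is that the cluster appears among random mutants with probability of at
  least 5%; lower tail P(X <= k) at p0 = 0.05. A small p-value means the
  cluster is unlikely to appear by chance.

The 95% confidence interval for k/n is the exact Clopper-Pearson
interval. No multiple-testing correction is applied across clusters; the
report flags when more than one cluster is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps

from .clustering import Cluster

DISAPPEAR_BOUNDARY = 0.95
APPEAR_BOUNDARY = 0.05


@dataclass(frozen=True)
class ClusterTest:
    cluster: Cluster
    direction: str  # "disappear" | "appear"
    k: int
    n: int
    p_value: float
    ci_low: float
    ci_high: float
    null_boundary: float

    @property
    def frequency(self) -> float:
        return self.k / self.n


def _check_kn(k: int, n: int) -> None:
    if n < 1:
        raise ValueError("need at least one mutant")
    if not 0 <= k <= n:
        raise ValueError(f"invalid overlap count k={k} for n={n}")


def overlap_count(
    target: Cluster, mutant_cluster_lists: list[list[Cluster]]
) -> tuple[int, int]:
    """(k, n): mutants with >= 1 cluster overlapping the target span."""
    n = len(mutant_cluster_lists)
    if n == 0:
        raise ValueError("empty mutant set")
    k = sum(
        1
        for clusters in mutant_cluster_lists
        if any(target.overlaps(c) for c in clusters)
    )
    return k, n


def test_disappear(k: int, n: int) -> tuple[float, tuple[float, float]]:
    """Upper-tail exact binomial p-value at p0 = 0.95, with 95% CI."""
    _check_kn(k, n)
    p = float(sps.binom.sf(k - 1, n, DISAPPEAR_BOUNDARY))
    return min(p, 1.0), binomial_ci(k, n)


def test_appear(k: int, n: int) -> tuple[float, tuple[float, float]]:
    """Lower-tail exact binomial p-value at p0 = 0.05, with 95% CI.

    P(X <= k; n, 0.05) is evaluated as the complementary upper tail
    P(n - X >= n - k; n, 0.95), so the appear/disappear symmetry identity
    holds exactly, not merely to rounding.
    """
    _check_kn(k, n)
    p = float(sps.binom.sf(n - k - 1, n, DISAPPEAR_BOUNDARY))
    return min(p, 1.0), binomial_ci(k, n)


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for k/n."""
    _check_kn(k, n)
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def cluster_test(
    target: Cluster, direction: str, mutant_cluster_lists: list[list[Cluster]]
) -> ClusterTest:
    """Full test record for one sequence-specific cluster."""
    k, n = overlap_count(target, mutant_cluster_lists)
    if direction == "disappear":
        p, ci = test_disappear(k, n)
        boundary = DISAPPEAR_BOUNDARY
    elif direction == "appear":
        p, ci = test_appear(k, n)
        boundary = APPEAR_BOUNDARY
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ClusterTest(
        cluster=target,
        direction=direction,
        k=k,
        n=n,
        p_value=p,
        ci_low=ci[0],
        ci_high=ci[1],
        null_boundary=boundary,
    )
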